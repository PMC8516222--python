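"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as PLINK 1 binary triples (.bed variant-major, magic bytes
6C 1B 01) or as plain-text dosage CSVs with a sidecar marker map. Everything
else is CSV/TSV/JSON with explicit validation that names the offending
row/column on failure.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError
from .geno_qc import GenotypeMatrix, Grm

PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes (variant-major): 00=hom A1, 01=missing, 10=het, 11=hom A2.
# We count A1 alleles, so code -> dose is 00->2, 10->1, 11->0, 01->NaN.
_CODE_TO_DOSE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSE_TO_CODE = {2.0: 0, 1.0: 2, 0.0: 3}


def write_plink(genotypes: GenotypeMatrix, prefix) -> None:
    """Write .bed/.bim/.fam under ``prefix`` (variant-major bed v1.00)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    m = genotypes.markers
    bim = pd.DataFrame({
        "chrom": m["chrom"], "snp_id": m["snp_id"], "cm": 0,
        "pos": m["pos"], "a1": m["a1"], "a2": m["a2"],
    })
    bim.to_csv(Path(f"{prefix}.bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": genotypes.animal_ids, "iid": genotypes.animal_ids,
        "pat": 0, "mat": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(Path(f"{prefix}.fam"), sep=" ", header=False, index=False)

    n = genotypes.n_animals
    n_bytes = (n + 3) // 4
    doses = genotypes.doses
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(PLINK_MAGIC)
        buf = np.zeros(n_bytes, dtype=np.uint8)
        for j in range(genotypes.n_markers):
            buf[:] = 0
            col = doses[:, j]
            for i in range(n):
                v = col[i]
                code = 1 if np.isnan(v) else _DOSE_TO_CODE[float(v)]
                buf[i >> 2] |= code << ((i & 3) * 2)
            fh.write(buf.tobytes())


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triple into a dose matrix."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        Path(f"{prefix}.bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    markers = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    fam = pd.read_csv(
        Path(f"{prefix}.fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"iid": str},
    )
    animal_ids = fam["iid"].to_numpy()
    n, n_snps = len(animal_ids), len(markers)
    n_bytes = (n + 3) // 4

    raw = Path(f"{prefix}.bed").read_bytes()
    if raw[:2] != PLINK_MAGIC[:2]:
        raise ParseError(f"{prefix}.bed: bad magic bytes {raw[:2].hex()}")
    if raw[2:3] != PLINK_MAGIC[2:3]:
        raise ParseError(f"{prefix}.bed: not variant-major (mode byte {raw[2]:#x})")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != n_bytes * n_snps:
        raise ParseError(
            f"{prefix}.bed: expected {n_bytes * n_snps} data bytes, found {body.size}"
        )
    blocks = body.reshape(n_snps, n_bytes)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_snps, n_bytes * 4)[:, :n]
    doses = _CODE_TO_DOSE[codes].T  # animals x markers
    return GenotypeMatrix(animal_ids, markers, doses)


def write_dosage_csv(genotypes: GenotypeMatrix, dosage_path, markers_path=None) -> None:
    """Dosage CSV (rows=animals, columns=snp ids) plus marker-map CSV."""
    df = pd.DataFrame(genotypes.doses, columns=genotypes.markers["snp_id"])
    df.insert(0, "animal_id", genotypes.animal_ids)
    df.to_csv(dosage_path, index=False, na_rep="NA")
    if markers_path is not None:
        genotypes.markers.to_csv(markers_path, index=False)


def read_dosage_csv(dosage_path, markers_path=None) -> GenotypeMatrix:
    """Read a dosage CSV; codes must be 0/1/2 or NA. Errors cite row/column."""
    df = pd.read_csv(dosage_path, dtype={"animal_id": str})
    if "animal_id" not in df.columns:
        raise ParseError(f"{dosage_path}: missing 'animal_id' column")
    animal_ids = df["animal_id"].to_numpy()
    snp_ids = [c for c in df.columns if c != "animal_id"]
    doses = df[snp_ids].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_na = df[snp_ids].isna().to_numpy()
    bad = np.isnan(doses) & ~raw_na
    bad |= ~np.isnan(doses) & ~np.isin(doses, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{dosage_path}: invalid dose {df[snp_ids].iat[r, c]!r} at "
            f"row {r + 2} (animal {animal_ids[r]}), column {snp_ids[c]}"
        )
    if markers_path is not None:
        markers = pd.read_csv(markers_path, dtype={"snp_id": str, "a1": str, "a2": str})
        missing = set(snp_ids) - set(markers["snp_id"])
        if missing:
            raise ParseError(f"{markers_path}: no map entry for {sorted(missing)[:5]}")
        markers = markers.set_index("snp_id").loc[snp_ids].reset_index()
    else:
        markers = pd.DataFrame({
            "snp_id": snp_ids, "chrom": 1,
            "pos": np.arange(1, len(snp_ids) + 1), "a1": "A", "a2": "B",
        })
    return GenotypeMatrix(animal_ids, markers, doses)


def write_grm(grm: Grm, prefix) -> None:
    """Dense GRM as TSV plus an id sidecar and a small JSON header."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(f"{prefix}.grm.tsv", grm.values, delimiter="\t", fmt="%.10g")
    Path(f"{prefix}.grm.ids").write_text("\n".join(grm.animal_ids) + "\n")
    Path(f"{prefix}.grm.json").write_text(json.dumps(
        {"kind": grm.kind, "denominator": grm.denominator, "n": grm.n}))


def read_grm(prefix) -> Grm:
    prefix = Path(prefix)
    values = np.loadtxt(f"{prefix}.grm.tsv", delimiter="\t", ndmin=2)
    ids = Path(f"{prefix}.grm.ids").read_text().split()
    meta = json.loads(Path(f"{prefix}.grm.json").read_text())
    return Grm(np.array(ids), values, kind=meta["kind"], denominator=meta["denominator"])


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str})
    required = {"station_id", "timestamp", "temp_c", "rh_pct"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: weather CSV needs columns {sorted(required)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_weather_csv(frames: Mapping[str, pd.DataFrame], path) -> None:
    parts = []
    for sid, frame in frames.items():
        part = frame.copy()
        part.insert(0, "station_id", sid)
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_coords_csv(path, id_column: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={id_column: str})
    required = {id_column, "lat", "lon"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: coordinates CSV needs columns {sorted(required)}")
    return df


def read_exposure_csv(path):
    from .climate import ExposureTable

    df = pd.read_csv(path, dtype={"animal_id": str})
    required = {"animal_id", "week", "weekly_thi", "hs_flag"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: exposure CSV needs columns {sorted(required)}")
    bad = ~df["hs_flag"].isin((0, 1))
    if bad.any():
        raise ParseError(f"{path}: non-binary hs_flag at row {int(np.argmax(bad.to_numpy())) + 2}")
    return ExposureTable(df)


def write_exposure_csv(exposure, path) -> None:
    exposure.table.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str})
    if "animal_id" not in df.columns:
        raise ParseError(f"{path}: missing 'animal_id' column")
    return df
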