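"""Plain-text file round-trips for every pipeline artifact.

Formats (all tab-separated or JSON/YAML text):

* expression / genotype: TSV, first column feature ID, header subject IDs
* pair list: two-column TSV (gene ID, SNP ID), no header
* ZMatrix: TSV with columns gene, snp, then one per tissue, plus a YAML
  sidecar ``<path>.meta.yaml`` holding per-tissue n, n_cov, d
* pairwise/single fits: one JSON file (also exportable as a TSV table)
* model: one JSON file; probabilities round-trip bit-exactly because
  JSON floats use shortest round-trip representation
* inference results: TSV with a # header recording the configuration
  set, alpha, and the model file hash
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import TissuePanel, ZMatrix
from .inference import InferenceResult
from .model import HTModel
from .pairwise import PairwiseFit, SingleFit

__all__ = [
    "read_matrix_tsv", "read_pairs_tsv", "write_zmatrix", "read_zmatrix",
    "write_fits", "read_fits", "fits_to_tsv", "save_model", "load_model",
    "write_results", "file_sha256",
]


def _atomic_write(path, text: str) -> None:
    """Write via a temp file + rename so failures leave no partial file."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".",
                               prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_matrix_tsv(path) -> pd.DataFrame:
    """Features x subjects TSV with feature IDs in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[~df.dtypes.map(
        lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        for col in bad:
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(row):
                raise ValueError(
                    f"{path}: non-numeric cell at row {row[0]!r}, "
                    f"column {col!r}")
        raise ValueError(f"{path}: non-numeric column(s) {list(bad)}")
    return df


def read_pairs_tsv(path) -> list:
    pairs = pd.read_csv(path, sep="\t", header=None,
                        names=["gene", "snp"], dtype=str)
    return list(pairs.itertuples(index=False, name=None))


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_zmatrix(zmat: ZMatrix, path) -> None:
    panel = zmat.panel
    df = pd.DataFrame(zmat.Z, columns=list(panel.tissue_names))
    df.insert(0, "snp", [s for _, s in zmat.pair_ids])
    df.insert(0, "gene", [g for g, _ in zmat.pair_ids])
    _atomic_write(path, df.to_csv(sep="\t", index=False,
                                  float_format="%.17g"))
    meta = {"tissues": [
        {"name": name, "n": int(n), "n_cov": int(c), "d": int(d)}
        for name, n, c, d in zip(panel.tissue_names, panel.n,
                                 panel.n_cov, panel.d)]}
    _atomic_write(_sidecar(path), yaml.safe_dump(meta, sort_keys=False))


def read_zmatrix(path) -> ZMatrix:
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing sidecar metadata file {side}; cannot interpret "
            "z-matrix without per-tissue degrees of freedom")
    meta = yaml.safe_load(side.read_text())
    panel = TissuePanel([t["name"] for t in meta["tissues"]],
                        [t["n"] for t in meta["tissues"]],
                        [t["n_cov"] for t in meta["tissues"]])
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "snp": str})
    cols = list(df.columns)
    if cols[:2] != ["gene", "snp"]:
        raise ValueError(f"{path}: first columns must be gene, snp")
    if cols[2:] != list(panel.tissue_names):
        raise ValueError(
            f"{path}: tissue columns {cols[2:]} do not match sidecar "
            f"tissues {list(panel.tissue_names)}")
    zcols = df[cols[2:]]
    for col in cols[2:]:
        if not np.issubdtype(zcols[col].dtype, np.number):
            bad = pd.to_numeric(zcols[col], errors="coerce").isna() \
                & zcols[col].notna()
            rownum = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"{path}: non-numeric cell at row {rownum + 2}, "
                f"column {col!r}")
    pair_ids = list(zip(df["gene"], df["snp"]))
    return ZMatrix(pair_ids, zcols.to_numpy(dtype=float), panel)


def write_fits(pair_fits, single_fits, path) -> None:
    doc = {
        "format": "hteqtl-fits",
        "version": 1,
        "pairs": [f.to_dict() for f in pair_fits],
        "singles": [s.to_dict() for s in single_fits],
    }
    _atomic_write(path, json.dumps(doc, indent=1))


def read_fits(path) -> tuple:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "hteqtl-fits":
        raise ValueError(f"{path}: not an hteqtl fits file")
    if int(doc.get("version", -1)) != 1:
        raise ValueError(f"{path}: unsupported fits version")
    pairs = [PairwiseFit.from_dict(d) for d in doc["pairs"]]
    singles = [SingleFit.from_dict(d) for d in doc["singles"]]
    return pairs, singles


def fits_to_tsv(pair_fits, path) -> None:
    rows = []
    for f in pair_fits:
        rows.append({
            "tissue_i": f.tissues[0], "tissue_j": f.tissues[1],
            "p00": f.p[0], "p01": f.p[1], "p10": f.p[2], "p11": f.p[3],
            "delta": f.delta, "sigma11": f.sigma[0, 0],
            "sigma12": f.sigma[0, 1], "sigma22": f.sigma[1, 1],
            "n_iter": f.n_iter, "converged": int(f.converged),
        })
    _atomic_write(path, pd.DataFrame(rows).to_csv(
        sep="\t", index=False, float_format="%.17g"))


def save_model(model: HTModel, path) -> None:
    _atomic_write(path, json.dumps(model.to_dict(), indent=1))


def load_model(path) -> HTModel:
    return HTModel.from_dict(json.loads(Path(path).read_text()))


def write_results(result: InferenceResult, path,
                  model_hash: str = "") -> None:
    header = (f"# config_set={result.config_set or 'unspecified'}\t"
              f"alpha={result.alpha}\tmodel_sha256={model_hash}\n")
    df = pd.DataFrame({
        "gene": [g for g, _ in result.pair_ids],
        "snp": [s for _, s in result.pair_ids],
        "lfdr": result.lfdr,
        "reject": result.reject.astype(int),
    })
    _atomic_write(path, header + df.to_csv(sep="\t", index=False,
                                           float_format="%.17g"))
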