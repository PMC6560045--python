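"""Readers and writers for peak lists, manifests and pipeline outputs.

Peak lists are plain CSV/TSV files with columns (mz, intensity) and an
optional header, or centroid-mode mzML (read by a small built-in reader
for the standard base64/zlib binary-array encoding).  A dataset
manifest is a TSV with columns ``sample_id``, ``path`` and optionally
``label``; paths are resolved relative to the manifest's directory.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Spectrum, SpectraSet

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_manifest",
    "load_dataset",
    "write_vlm_table",
    "read_vlm_table",
    "write_feature_matrix",
    "read_feature_matrix",
]

_DIALECT_SEP = {"csv": ",", "tsv": "\t"}


def _guess_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".tab", ".txt"):
        return "tsv"
    if suffix == ".mzml":
        return "mzml"
    return "csv"


def read_peaklist(
    path,
    dialect: Optional[str] = None,
    id: Optional[str] = None,
    label: Optional[str] = None,
    merge_scans: bool = False,
) -> Spectrum:
    """Read one centroided peak list into a :class:`Spectrum`.

    CSV/TSV files must have two numeric columns (mz, intensity); a
    non-numeric first row is treated as a header.  Unsorted input is sorted
    with a warning.  Zero-intensity rows are retained — thresholding is the
    detector's job.  For mzML, multi-scan files are rejected unless
    ``merge_scans`` is set, in which case scans are pooled into one list.
    """
    path = Path(path)
    if dialect is None:
        dialect = _guess_dialect(path)
    if dialect == "mzml":
        mz, inten = _read_mzml(path, merge_scans)
    elif dialect in _DIALECT_SEP:
        mz, inten = _read_delimited(path, _DIALECT_SEP[dialect])
    else:
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    if np.any(mz <= 0):
        raise ValueError(f"{path}: non-positive m/z values")
    if mz.size and np.any(np.diff(mz) < 0):
        warnings.warn(f"{path}: peaks out of m/z order; sorting", stacklevel=2)
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
    return Spectrum(id=id or path.stem, mz=mz, intensity=inten, label=label)


def _read_delimited(path: Path, sep: str):
    mzs, intens = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}, line {lineno}: expected 2 columns, got {len(row)}")
            try:
                mz, inten = float(row[0]), float(row[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}, line {lineno}: unparseable row {row!r}") from None
            mzs.append(mz)
            intens.append(inten)
    return np.asarray(mzs, dtype=np.float64), np.asarray(intens, dtype=np.float64)


_MS_ACC = {
    "mz": "MS:1000514",
    "intensity": "MS:1000515",
    "f64": "MS:1000523",
    "f32": "MS:1000521",
    "zlib": "MS:1000574",
    "centroid": "MS:1000127",
    "profile": "MS:1000128",
}


def _decode_binary_array(elem) -> np.ndarray:
    import base64
    import zlib as _zlib

    accessions = {
        cv.get("accession")
        for cv in elem.iter()
        if cv.tag.endswith("cvParam")
    }
    binary = next(e for e in elem.iter() if e.tag.endswith("}binary") or e.tag == "binary")
    raw = base64.b64decode(binary.text or "")
    if _MS_ACC["zlib"] in accessions:
        raw = _zlib.decompress(raw)
    dtype = np.float32 if _MS_ACC["f32"] in accessions else np.float64
    return np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).astype(np.float64)


def _read_mzml(path: Path, merge_scans: bool):
    """Minimal centroid-mzML reader (base64/zlib binary arrays via lxml)."""
    from lxml import etree

    scans = []
    for _, spectrum in etree.iterparse(str(path), tag="{*}spectrum"):
        accessions = {
            cv.get("accession")
            for cv in spectrum.iter()
            if cv.tag.endswith("cvParam")
        }
        if _MS_ACC["profile"] in accessions and _MS_ACC["centroid"] not in accessions:
            raise ValueError(f"{path}: profile-mode spectra are not supported")
        mz = inten = None
        for array in spectrum.iter("{*}binaryDataArray"):
            accs = {cv.get("accession") for cv in array.iter() if cv.tag.endswith("cvParam")}
            if _MS_ACC["mz"] in accs:
                mz = _decode_binary_array(array)
            elif _MS_ACC["intensity"] in accs:
                inten = _decode_binary_array(array)
        if mz is None or inten is None:
            raise ValueError(f"{path}: spectrum without m/z or intensity array")
        scans.append((mz, inten))
        spectrum.clear()
    if not scans:
        return np.empty(0), np.empty(0)
    if len(scans) > 1 and not merge_scans:
        raise ValueError(
            f"{path}: {len(scans)} scans found; pass merge_scans=True to pool them"
        )
    mz = np.concatenate([s[0] for s in scans])
    inten = np.concatenate([s[1] for s in scans])
    return mz, inten


def write_peaklist(spectrum: Spectrum, path, dialect: str = "csv") -> None:
    """Write a spectrum as a two-column (mz, intensity) CSV/TSV with header."""
    sep = _DIALECT_SEP[dialect]
    df = pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity})
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_manifest(path) -> pd.DataFrame:
    """Read a TSV manifest (sample_id, path[, label]); paths resolved to absolute."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    df["path"] = [str((path.parent / p).resolve()) for p in df["path"]]
    if "label" not in df.columns:
        df["label"] = None
    return df[["sample_id", "path", "label"]]


def load_dataset(manifest_path) -> SpectraSet:
    """Load all spectra listed in a manifest into a :class:`SpectraSet`."""
    manifest = read_manifest(manifest_path)
    spectra = []
    for row in manifest.itertuples(index=False):
        label = None if row.label is None or (isinstance(row.label, float) and np.isnan(row.label)) else str(row.label)
        spectra.append(read_peaklist(row.path, id=str(row.sample_id), label=label))
    return SpectraSet(tuple(spectra))


def write_vlm_table(vlms, path) -> None:
    """Write a lock-mass table: one row per VLM with its window and members.

    Columns: vlm_mz, window_lo, window_hi, then one matched-m/z column per
    spectrum id (empty where the VLM has no member in that spectrum, which
    can happen in alignment mode).
    """
    ids = list(vlms.spectrum_ids)
    rows = []
    for v in vlms:
        lo, hi = vlms.window(v.mz)
        row = {"vlm_mz": v.mz, "window_lo": lo, "window_hi": hi}
        member_by_sigma = {p.spectrum_index: p.mz for p in v.members}
        for sigma, sid in enumerate(ids):
            row[sid] = member_by_sigma.get(sigma, np.nan)
        rows.append(row)
    columns = ["vlm_mz", "window_lo", "window_hi", *ids]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.12g")


def read_vlm_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_matrix(features: pd.DataFrame, path, labels: Optional[Sequence] = None) -> None:
    """Write a feature matrix (rows = samples, columns = alignment points).

    Column labels are the alignment-point m/z values rounded to 6 decimals;
    absent peaks are 0.  An optional ``label`` column is appended.
    """
    out = features.copy()
    out.columns = [f"{float(c):.6f}" if not isinstance(c, str) else c for c in out.columns]
    if labels is not None:
        out["label"] = list(labels)
    out.to_csv(path, index=True, index_label="sample_id", float_format="%.12g")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    return df
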