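"""Tab-separated I/O for exposures, signature definitions and catalogs.

TSV with a header row is the canonical tabular dialect; structured results
(fits, tests, Monte-Carlo reports) are written as JSON with a provenance
block carrying the configuration and seed that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExposureData, MutationCatalog, SignatureCatalog

__all__ = [
    "read_exposures", "write_exposures",
    "read_signatures", "write_signatures",
    "read_catalog", "write_catalog",
    "write_json",
]

_META_COLS = ["patient_id", "group"]


def read_exposures(path, zero_columns: str = "error",
                   ref_group=None) -> ExposureData:
    """Read an exposure TSV (patient_id, group, then K count columns).

    Rows are normalised so patients are contiguous with the reference
    group first; integer and non-negativity constraints are enforced with
    errors naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"exposure file lacks column(s) {missing}")
    sig_cols = [c for c in df.columns if c not in _META_COLS]
    if len(sig_cols) < 2:
        raise ValueError("need at least two signature columns")
    counts = df[sig_cols].to_numpy()
    bad = np.argwhere(~np.isfinite(counts.astype(float))
                      | (counts.astype(float) < 0)
                      | (counts.astype(float) != np.round(counts.astype(float))))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"invalid count at row {r + 1}, column {sig_cols[c]!r}: "
            f"{counts[r, c]!r} (must be a non-negative integer)"
        )
    data = ExposureData(counts.astype(np.int64),
                        df["patient_id"].to_numpy(),
                        df["group"].to_numpy(),
                        sig_cols)
    return data.sort_normalised(ref_group=ref_group).validate(zero_columns)


def write_exposures(data: ExposureData, path) -> None:
    data.to_frame().to_csv(path, sep="\t", index=False)


def read_signatures(path) -> SignatureCatalog:
    """Read a COSMIC-style signature-definition TSV.

    First column holds category names (e.g. ``A[C>A]A``); remaining
    columns are signatures.  Columns must sum to 1 within 1e-4 (they are
    renormalised exactly); rows are matched by category name downstream,
    so their order is preserved but not semantically meaningful.
    """
    df = pd.read_csv(path, sep="\t")
    cat_col = df.columns[0]
    cats = df[cat_col].astype(str).tolist()
    sigs = [c for c in df.columns if c != cat_col]
    S = df[sigs].to_numpy(dtype=float)
    if np.any(~np.isfinite(S)):
        raise ValueError("signature definitions contain NaN/inf")
    return SignatureCatalog(S, cats, sigs)


def write_signatures(catalog: SignatureCatalog, path) -> None:
    df = pd.DataFrame(catalog.S, columns=catalog.signature_names)
    df.insert(0, "category", catalog.category_names)
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path, signatures: SignatureCatalog | None = None) -> MutationCatalog:
    """Read a mutation-catalog TSV (category, patient_id row, group row? — no:
    columns are observations identified by ``patient_id:group`` headers).

    Layout: first column ``category``; each remaining column is one
    observation named ``<patient>:<group>`` holding category counts.  If a
    ``SignatureCatalog`` is given, rows are re-ordered by category name to
    match it.
    """
    df = pd.read_csv(path, sep="\t")
    cat_col = df.columns[0]
    cats = df[cat_col].astype(str).tolist()
    obs = [c for c in df.columns if c != cat_col]
    pat, grp = [], []
    for c in obs:
        if ":" not in c:
            raise ValueError(f"observation column {c!r} is not 'patient:group'")
        a, b = c.split(":", 1)
        pat.append(a)
        grp.append(b)
    V = df[obs].to_numpy()
    if signatures is not None:
        pos = {c: i for i, c in enumerate(cats)}
        missing = [c for c in signatures.category_names if c not in pos]
        if missing:
            raise ValueError(f"catalog lacks categories {missing[:3]}...")
        order = [pos[c] for c in signatures.category_names]
        V = V[order]
        cats = list(signatures.category_names)
    return MutationCatalog(V, cats, np.array(pat), np.array(grp))


def write_catalog(catalog: MutationCatalog, path) -> None:
    cols = [f"{p}:{g}" for p, g in zip(catalog.patient_id, catalog.group)]
    df = pd.DataFrame(catalog.V, columns=cols)
    df.insert(0, "category", catalog.category_names)
    df.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path, provenance: dict | None = None) -> None:
    """Write a result JSON, embedding the producing config/seed."""
    out = dict(obj)
    if provenance is not None:
        out["provenance"] = provenance

    def _default(x):
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, Path):
            return str(x)
        raise TypeError(f"not JSON-serialisable: {type(x)}")

    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_default)
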