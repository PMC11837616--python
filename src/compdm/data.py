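"""Data containers and design-matrix construction.

The response is an N x K matrix of non-negative integer signature-exposure
counts, one row per observation (a patient/group combination).  The default
study design is two matched groups per patient (e.g. clonal vs subclonal
mutations), giving N = 2 * N_s observations; unmatched designs are accepted
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExposureData",
    "DesignSet",
    "SignatureCatalog",
    "MutationCatalog",
    "ModelSpec",
    "VARIANTS",
    "build_design",
]


# ---------------------------------------------------------------------------
# model variants
# ---------------------------------------------------------------------------

#: variant name -> (likelihood, random-effect structure, precision structure)
#: re_structure: none | scalar | diagonal | full
#: precision_structure: none | single | by_d | per_patient
VARIANTS: dict[str, tuple[str, str, str]] = {
    "diagREDM": ("dm", "diagonal", "by_d"),
    "fullREDM": ("dm", "full", "by_d"),
    "singleREDM": ("dm", "scalar", "by_d"),
    "fullREM": ("multinomial", "full", "none"),
    "FEDMsinglelambda": ("dm", "none", "single"),
    "diagREDMpatientlambda": ("dm", "diagonal", "per_patient"),
}


@dataclass(frozen=True)
class ModelSpec:
    """A model variant together with the reference-category choice."""

    variant: str = "diagREDM"
    ref_category: int | None = None  # None -> last column

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown model variant {self.variant!r}; "
                f"valid names: {', '.join(sorted(VARIANTS))}"
            )

    @property
    def likelihood(self) -> str:
        return VARIANTS[self.variant][0]

    @property
    def re_structure(self) -> str:
        return VARIANTS[self.variant][1]

    @property
    def precision_structure(self) -> str:
        return VARIANTS[self.variant][2]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExposureData:
    """N x K signature-exposure counts with patient and group metadata.

    Rows are kept sorted so that each patient's observations are contiguous
    and the reference group comes first; the per-observation totals ``T``
    are derived from the row sums.
    """

    Y: np.ndarray
    patient_id: np.ndarray
    group: np.ndarray
    signature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.Y = np.asarray(self.Y)
        if self.Y.ndim != 2 or self.Y.shape[1] < 1:
            raise ValueError("Y must be an N x K matrix")
        if np.any(self.Y < 0) or not np.allclose(self.Y, np.round(self.Y)):
            bad = np.argwhere((self.Y < 0) | ~np.isclose(self.Y, np.round(self.Y)))
            r, c = bad[0]
            raise ValueError(
                f"counts must be non-negative integers; offending entry at "
                f"row {r}, column {c} ({self.Y[r, c]!r})"
            )
        self.Y = self.Y.astype(np.int64)
        self.patient_id = np.asarray(self.patient_id)
        self.group = np.asarray(self.group)
        if len(self.patient_id) != self.Y.shape[0] or len(self.group) != self.Y.shape[0]:
            raise ValueError("patient_id/group length must match the number of rows")
        if not self.signature_names:
            self.signature_names = [f"S{k + 1}" for k in range(self.Y.shape[1])]
        if len(self.signature_names) != self.Y.shape[1]:
            raise ValueError("signature_names length must equal K")

    @property
    def n_obs(self) -> int:
        return self.Y.shape[0]

    @property
    def n_categories(self) -> int:
        return self.Y.shape[1]

    @property
    def T(self) -> np.ndarray:
        """Per-observation totals (mutational toll)."""
        return self.Y.sum(axis=1)

    def validate(self, zero_columns: str = "error") -> "ExposureData":
        """Check invariants that the models rely on.

        ``zero_columns`` controls what happens when a signature has zero
        counts in every observation ("error" or "warn"): such signatures
        cannot be placed on the log-ratio scale and should be dropped.
        """
        if self.n_categories < 2:
            raise ValueError("modelling requires at least two signature columns")
        if np.any(self.T < 1):
            raise ValueError("every observation must have total count >= 1")
        zero = np.where(self.Y.sum(axis=0) == 0)[0]
        if zero.size:
            names = [self.signature_names[k] for k in zero]
            msg = (
                f"signature column(s) {names} are zero in all observations; "
                "drop them before fitting"
            )
            if zero_columns == "error":
                raise ValueError(msg)
            warnings.warn(msg)
        pg = list(zip(self.patient_id.tolist(), self.group.tolist()))
        if len(set(pg)) != len(pg):
            raise ValueError("duplicate (patient, group) rows")
        counts = pd.Series(self.patient_id).groupby(pd.Series(self.patient_id)).size()
        if counts.nunique() > 1:
            warnings.warn(
                "unmatched design: patients have differing numbers of "
                "observations; the model applies but pairing is not used"
            )
        return self

    def sort_normalised(self, ref_group=None) -> "ExposureData":
        """Rows reordered so patients are contiguous, reference group first."""
        groups_seen = list(pd.unique(self.group))
        if ref_group is None:
            ref_group = groups_seen[0]
        elif ref_group not in groups_seen:
            raise ValueError(f"reference group {ref_group!r} not present")
        group_rank = {g: (0 if g == ref_group else i + 1) for i, g in enumerate(groups_seen)}
        patients_seen = {p: i for i, p in enumerate(pd.unique(self.patient_id))}
        order = sorted(
            range(self.n_obs),
            key=lambda j: (patients_seen[self.patient_id[j]], group_rank[self.group[j]]),
        )
        return ExposureData(
            self.Y[order],
            self.patient_id[order],
            self.group[order],
            list(self.signature_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Y, columns=self.signature_names)
        df.insert(0, "group", self.group)
        df.insert(0, "patient_id", self.patient_id)
        return df


@dataclass(frozen=True)
class DesignSet:
    """Fixed-effect (X), random-effect grouping (Z) and precision (D) designs."""

    X: np.ndarray
    Z: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        X, Z, D = (np.asarray(m, dtype=float) for m in (self.X, self.Z, self.D))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "D", D)
        n = X.shape[0]
        if Z.shape[0] != n or D.shape[0] != n:
            raise ValueError(
                f"design row counts differ: X has {n}, Z {Z.shape[0]}, D {D.shape[0]}"
            )
        if not np.all((Z == 0) | (Z == 1)) or not np.all(Z.sum(axis=1) == 1):
            raise ValueError("Z must be 0/1 with exactly one 1 per row")

    @property
    def n_patients(self) -> int:
        return self.Z.shape[1]

    @property
    def patient_index(self) -> np.ndarray:
        """Per-observation patient column index implied by Z."""
        return self.Z.argmax(axis=1)


def build_design(data: ExposureData, ref_group=None) -> DesignSet:
    """Default two-group matched design: X = [1, group], Z = patient dummy, D = X.

    The first-seen group (or ``ref_group``) is the reference (coded 0).
    """
    groups = list(pd.unique(data.group))
    if ref_group is None:
        ref_group = groups[0]
    if len(groups) < 2:
        ind = np.zeros(data.n_obs)
        X = np.ones((data.n_obs, 1))
    else:
        if len(groups) > 2:
            # one indicator per non-reference group
            others = [g for g in groups if g != ref_group]
            X = np.ones((data.n_obs, 1 + len(others)))
            for i, g in enumerate(others):
                X[:, 1 + i] = (data.group == g).astype(float)
        else:
            other = [g for g in groups if g != ref_group][0]
            ind = (data.group == other).astype(float)
            X = np.column_stack([np.ones(data.n_obs), ind])
    patients = list(pd.unique(data.patient_id))
    pat_idx = {p: i for i, p in enumerate(patients)}
    Z = np.zeros((data.n_obs, len(patients)))
    for j, p in enumerate(data.patient_id):
        Z[j, pat_idx[p]] = 1.0
    return DesignSet(X=X, Z=Z, D=X.copy())


# ---------------------------------------------------------------------------
# signature catalogs
# ---------------------------------------------------------------------------

@dataclass
class SignatureCatalog:
    """F x K matrix of per-signature category probabilities (COSMIC-style)."""

    S: np.ndarray
    category_names: list[str]
    signature_names: list[str]

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2:
            raise ValueError("S must be an F x K matrix")
        if np.any(self.S < 0) or np.any(~np.isfinite(self.S)):
            raise ValueError("signature definitions must be non-negative and finite")
        sums = self.S.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-4):
            bad = self.signature_names[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValueError(
                f"signature column {bad!r} sums to {sums[np.argmax(np.abs(sums - 1.0))]:.4f}, "
                "not 1 (within 1e-4)"
            )
        self.S = self.S / sums  # renormalise the small residual
        if len(self.category_names) != self.S.shape[0]:
            raise ValueError("category_names length must equal F")
        if len(self.signature_names) != self.S.shape[1]:
            raise ValueError("signature_names length must equal K")

    def subset(self, active: list[str]) -> "SignatureCatalog":
        missing = [a for a in active if a not in self.signature_names]
        if missing:
            raise ValueError(f"unknown signature(s): {missing}")
        idx = [self.signature_names.index(a) for a in active]
        return SignatureCatalog(self.S[:, idx], list(self.category_names), list(active))


@dataclass
class MutationCatalog:
    """F x N matrix of categorised mutation counts with observation metadata."""

    V: np.ndarray
    category_names: list[str]
    patient_id: np.ndarray
    group: np.ndarray

    def __post_init__(self):
        self.V = np.asarray(self.V)
        if self.V.ndim != 2:
            raise ValueError("V must be an F x N matrix")
        if np.any(self.V < 0) or not np.allclose(self.V, np.round(self.V)):
            raise ValueError("mutation counts must be non-negative integers")
        self.V = self.V.astype(np.int64)
        if len(self.category_names) != self.V.shape[0]:
            raise ValueError("category_names length must equal F")
        self.patient_id = np.asarray(self.patient_id)
        self.group = np.asarray(self.group)
        if len(self.patient_id) != self.V.shape[1] or len(self.group) != self.V.shape[1]:
            raise ValueError("metadata length must equal the number of observations")

    @property
    def T(self) -> np.ndarray:
        return self.V.sum(axis=0)
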