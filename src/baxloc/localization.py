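"""Relative localization scoring and BAX-protection classification.

The relative localization of an analyte is the quotient of its relative
mitochondrial protein (per COX IV) over its relative cytosolic protein (per
beta-ACTIN); high values mean a shift towards the mitochondria and hence
increased apoptosis predisposition.  All statistics are carried on log10
scale.  A tumor whose BAX localization drops by about two log10 units
relative to the matched non-tumor tissue is called BAX-protected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InsufficientCohortError,
    InvalidQuantificationError,
    PairingError,
)

CATEGORIES = ("low_extreme", "low_moderate", "high_moderate", "high_extreme")

#: default log10 threshold separating a protected (~2-log) shift from noise
PROTECTION_THRESHOLD = -1.0


@dataclass(frozen=True)
class LocalizationRecord:
    """Per sample x analyte relative localization."""

    patient_id: str
    tissue: str  # "tumor" | "non_tumor"
    analyte: str
    rel_mito: float
    rel_cyto: float

    def __post_init__(self) -> None:
        for name in ("rel_mito", "rel_cyto"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidQuantificationError(
                    f"{name} must be finite and > 0, got {v!r} "
                    f"({self.patient_id}, {self.analyte})")

    @property
    def rel_loc(self) -> float:
        return self.rel_mito / self.rel_cyto

    @property
    def log10_rel_loc(self) -> float:
        return math.log10(self.rel_loc)


@dataclass(frozen=True)
class ProtectionCall:
    """Per-patient classification output."""

    patient_id: str
    mito_bax_category: str
    delta_log10: float
    label: str  # "protected" | "non_protected"


@dataclass(frozen=True)
class CarbonateRecord:
    """Carbonate-extraction split of the mitochondrial pool of one sample."""

    sample_id: str
    integral_amount: float   # carbonate pellet, OMM-integral
    associated_amount: float  # carbonate supernatant, OMM-associated

    def __post_init__(self) -> None:
        if not (self.integral_amount > 0 and self.associated_amount > 0):
            raise InvalidQuantificationError(
                f"carbonate amounts must be > 0 ({self.sample_id})")

    @property
    def distribution(self) -> float:
        return self.integral_amount / self.associated_amount

    @property
    def log10_distribution(self) -> float:
        return math.log10(self.distribution)


def relative_localization(rel_mito: float, rel_cyto: float,
                          patient_id: str = "", tissue: str = "",
                          analyte: str = "BAX") -> LocalizationRecord:
    """Quotient of relative mitochondrial over relative cytosolic protein."""
    return LocalizationRecord(patient_id=patient_id, tissue=tissue,
                              analyte=analyte, rel_mito=rel_mito, rel_cyto=rel_cyto)


def delta_localization(tumor: LocalizationRecord,
                       nontumor: LocalizationRecord) -> float:
    """Tumor minus non-tumor log10 relative localization (negative = cytosolic shift)."""
    if tumor.patient_id != nontumor.patient_id or tumor.analyte != nontumor.analyte:
        raise PairingError(
            f"cannot pair ({tumor.patient_id}, {tumor.analyte}) with "
            f"({nontumor.patient_id}, {nontumor.analyte})")
    return tumor.log10_rel_loc - nontumor.log10_rel_loc


def carbonate_distribution(integral: float, associated: float,
                           sample_id: str = "") -> CarbonateRecord:
    """OMM-integral over OMM-associated amount (carbonate pellet / supernatant)."""
    return CarbonateRecord(sample_id=sample_id, integral_amount=integral,
                           associated_amount=associated)


def score_localization(rel_table: pd.DataFrame) -> pd.DataFrame:
    """Long-format localization table from marker-normalized amounts.

    Input columns: sample_id, tissue (T/N or tumor/non_tumor), analyte,
    rel_mito, rel_cyto.  Output adds patient_id, rel_loc and log10_rel_loc.
    Patient ids are the sample ids with a trailing ``_T`` / ``_N`` stripped.
    """
    tissue_map = {"T": "tumor", "N": "non_tumor",
                  "tumor": "tumor", "non_tumor": "non_tumor"}
    rows = []
    for r in rel_table.itertuples(index=False):
        sid = str(r.sample_id)
        pid = sid[:-2] if sid.endswith(("_T", "_N")) else sid
        rec = LocalizationRecord(patient_id=pid, tissue=tissue_map[str(r.tissue)],
                                 analyte=r.analyte, rel_mito=float(r.rel_mito),
                                 rel_cyto=float(r.rel_cyto))
        rows.append((rec.patient_id, rec.tissue, rec.analyte, rec.rel_mito,
                     rec.rel_cyto, rec.rel_loc, rec.log10_rel_loc))
    return pd.DataFrame(rows, columns=["patient_id", "tissue", "analyte",
                                       "rel_mito", "rel_cyto", "rel_loc",
                                       "log10_rel_loc"])


def category_sizes(n: int) -> tuple[int, int, int, int]:
    """Balanced sizes of the four ordered categories.

    Each category receives floor(n/4); the remainder goes to the middle
    (moderate) categories first, then outward: low_moderate, high_moderate,
    high_extreme.  n=34 gives (8, 9, 9, 8).
    """
    if n < 4:
        raise InsufficientCohortError(f"need >= 4 patients, got {n}")
    base = n // 4
    sizes = [base] * 4
    for slot in (1, 2, 3)[: n % 4]:
        sizes[slot] += 1
    return tuple(sizes)


def categorize_by_nontumor_mito_bax(values: pd.Series) -> pd.Series:
    """Rank-partition patients into four ordered mitochondrial-BAX categories.

    ``values`` maps patient_id to non-tumor relative mitochondrial BAX.
    Patients are ordered by (value, patient_id) — a stable order under ties —
    and split into low_extreme .. high_extreme with balanced sizes
    (remainder to the middle categories first).
    """
    sizes = category_sizes(len(values))
    order = sorted(values.items(), key=lambda kv: (kv[1], kv[0]))
    labels: dict[str, str] = {}
    pos = 0
    for cat, size in zip(CATEGORIES, sizes):
        for pid, _ in order[pos:pos + size]:
            labels[pid] = cat
        pos += size
    return pd.Series({pid: labels[pid] for pid in values.index}, name="category")


def _auto_threshold(deltas: np.ndarray) -> float:
    """Two-component split of the deltas: 1-D 2-means, threshold at the
    midpoint of the two cluster centers (threshold-free alternative)."""
    lo, hi = float(deltas.min()), float(deltas.max())
    c = np.array([lo, hi])
    for _ in range(100):
        assign = np.abs(deltas[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([deltas[assign == j].mean() if np.any(assign == j) else c[j]
                        for j in range(2)])
        if np.allclose(new, c):
            break
        c = new
    return float(c.mean())


def classify_protection(loc_table: pd.DataFrame,
                        threshold_log10: float | str = PROTECTION_THRESHOLD
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BAX-protection calls for a paired cohort.

    ``loc_table`` is the :func:`score_localization` output.  For every patient
    the BAX shift delta = log10 rel_loc(tumor) - log10 rel_loc(non-tumor) is
    computed; a patient is labelled protected iff delta <= threshold
    (inclusive).  ``threshold_log10="auto"`` derives the threshold from a
    two-component split of the deltas.  Returns the per-patient calls
    (patient_id, category, delta_log10, label) and a per-category summary of
    protected / non-protected counts.
    """
    bax = loc_table[loc_table["analyte"] == "BAX"]
    pivot_loc = bax.pivot_table(index="patient_id", columns="tissue",
                                values="log10_rel_loc", aggfunc="first")
    if ("tumor" not in pivot_loc.columns or "non_tumor" not in pivot_loc.columns
            or pivot_loc.isna().any().any()):
        missing = (list(pivot_loc.index[pivot_loc.isna().any(axis=1)])
                   if len(pivot_loc.columns) == 2 else list(pivot_loc.index))
        raise PairingError(f"patients without a tumor/non-tumor BAX pair: {missing}")
    deltas = (pivot_loc["tumor"] - pivot_loc["non_tumor"]).sort_index()

    nontumor_mito = bax[bax["tissue"] == "non_tumor"].set_index("patient_id")["rel_mito"]
    categories = categorize_by_nontumor_mito_bax(nontumor_mito)

    if threshold_log10 == "auto":
        threshold = _auto_threshold(deltas.to_numpy())
    else:
        threshold = float(threshold_log10)
    calls = pd.DataFrame({
        "patient_id": deltas.index,
        "category": categories.reindex(deltas.index).to_numpy(),
        "delta_log10": deltas.to_numpy(),
        "label": np.where(deltas.to_numpy() <= threshold,
                          "protected", "non_protected"),
    })
    summary = (calls.groupby(["category", "label"]).size()
               .unstack(fill_value=0)
               .reindex(list(CATEGORIES))
               .fillna(0).astype(int))
    for col in ("protected", "non_protected"):
        if col not in summary.columns:
            summary[col] = 0
    return calls, summary[["protected", "non_protected"]]


def carbonate_table(amounts: pd.DataFrame) -> pd.DataFrame:
    """Carbonate distribution per sample from calibrated amounts.

    Expects rows with fraction ``carb_pellet`` (OMM-integral) and ``carb_sup``
    (OMM-associated) for analyte BAX.
    """
    carb = amounts[(amounts["fraction"].isin(["carb_pellet", "carb_sup"]))
                   & (amounts["analyte"] == "BAX")]
    rows = []
    for sid, grp in carb.groupby("sample_id", sort=True):
        by = {r.fraction: r.amount for r in grp.itertuples(index=False)}
        if "carb_pellet" not in by or "carb_sup" not in by:
            raise PairingError(f"sample {sid}: incomplete carbonate pair")
        rec = CarbonateRecord(sample_id=sid, integral_amount=by["carb_pellet"],
                              associated_amount=by["carb_sup"])
        rows.append((sid, rec.integral_amount, rec.associated_amount,
                     rec.distribution, rec.log10_distribution))
    return pd.DataFrame(rows, columns=["sample_id", "integral_amount",
                                       "associated_amount", "distribution",
                                       "log10_distribution"])
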