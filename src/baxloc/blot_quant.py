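"""Standard-curve calibration of western-blot lane tables.

Densitometry intensities are only comparable within a blot (and antibody):
every blot therefore carries a titration of one common HeLa whole-cell-lysate
standard per analyte.  Fitting that titration per blot x analyte and
back-calculating sample bands through it expresses every band in
HeLa-equivalent units, cancelling the arbitrary per-blot gain, after which
amounts are marker-normalized (COX IV for the mitochondrial fraction,
beta-ACTIN for the cytosolic fraction) into relative protein levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InsufficientStandardsError,
    MissingMarkerError,
    NonMonotoneStandardError,
    NonpositiveAmountError,
)

log = logging.getLogger(__name__)

MITO_MARKER = "COXIV"
CYTO_MARKER = "ACTIN"


@dataclass(frozen=True)
class BlotLane:
    """One quantified band on one blot (sample band or titration standard)."""

    blot_id: str
    lane_index: int
    analyte: str
    fraction: str  # mito | cyto | carb_sup | carb_pellet | std
    sample_id: str = ""
    tissue: str = "NA"
    std_amount: float = np.nan
    intensity: float = np.nan

    def __post_init__(self) -> None:
        if not self.intensity >= 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
        if self.fraction == "std" and not self.std_amount > 0:
            raise ValueError("standard lanes must carry std_amount > 0")


@dataclass(frozen=True)
class StandardCurve:
    """Affine fit intensity = slope * amount + intercept for one blot x analyte."""

    blot_id: str
    analyte: str
    amounts: tuple[float, ...]
    intensities: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float

    def quantify(self, intensity: float) -> tuple[float, bool]:
        """Back-calculated amount and an extrapolation flag.

        The flag marks amounts outside the titration range; they are kept
        (extreme localizations span log scales) but reported.
        """
        amount = (intensity - self.intercept) / self.slope
        if amount <= 0:
            raise NonpositiveAmountError(
                f"blot {self.blot_id}, {self.analyte}: intensity {intensity:g} "
                f"back-calculates to nonpositive amount {amount:g}")
        extrapolated = not (min(self.amounts) <= amount <= max(self.amounts))
        return float(amount), extrapolated


def _as_std_arrays(std_lanes) -> tuple[str, str, np.ndarray, np.ndarray]:
    if isinstance(std_lanes, pd.DataFrame):
        df = std_lanes
        blots = df["blot_id"].unique()
        analytes = df["analyte"].unique()
        amounts = df["std_amount"].to_numpy(float)
        intens = df["intensity"].to_numpy(float)
    else:
        lanes = list(std_lanes)
        blots = sorted({l.blot_id for l in lanes})
        analytes = sorted({l.analyte for l in lanes})
        amounts = np.array([l.std_amount for l in lanes], float)
        intens = np.array([l.intensity for l in lanes], float)
    if len(blots) != 1 or len(analytes) != 1:
        raise ValueError("standard lanes must come from one blot and one analyte")
    return str(blots[0]), str(analytes[0]), amounts, intens


def fit_standard_curve(std_lanes, through_origin: bool = False) -> StandardCurve:
    """Ordinary-least-squares line through the titration points.

    The affine form tolerates a constant background offset; a through-origin
    fit is available for blots known to be background-subtracted.  A fitted
    slope <= 0 means the titration is not monotone increasing and the blot
    cannot be calibrated.
    """
    blot_id, analyte, x, y = _as_std_arrays(std_lanes)
    if x.size < 3:
        raise InsufficientStandardsError(
            f"blot {blot_id}, {analyte}: {x.size} standard lanes (< 3)")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    if slope <= 0:
        raise NonMonotoneStandardError(
            f"blot {blot_id}, {analyte}: fitted slope {slope:g} <= 0")
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    order = np.argsort(x, kind="stable")
    return StandardCurve(blot_id=blot_id, analyte=analyte,
                         amounts=tuple(x[order]), intensities=tuple(y[order]),
                         slope=slope, intercept=intercept, r_squared=r2)


def quantify_band(lane: BlotLane, curve: StandardCurve) -> tuple[float, bool]:
    """Standardized amount (HeLa-equivalent units) for one sample band."""
    if lane.blot_id != curve.blot_id or lane.analyte != curve.analyte:
        raise ValueError(
            f"lane ({lane.blot_id}, {lane.analyte}) does not match curve "
            f"({curve.blot_id}, {curve.analyte})")
    return curve.quantify(lane.intensity)


def fit_all_curves(lanes: pd.DataFrame,
                   through_origin: bool = False) -> dict[tuple[str, str], StandardCurve]:
    """Standard curve per (blot_id, analyte) from the table's titration lanes."""
    std = lanes[lanes["fraction"] == "std"]
    curves = {}
    for (blot, analyte), grp in std.groupby(["blot_id", "analyte"], sort=True):
        curves[(blot, analyte)] = fit_standard_curve(grp, through_origin=through_origin)
    return curves


def calibrate_lanes(lanes: pd.DataFrame,
                    through_origin: bool = False) -> pd.DataFrame:
    """Convert every sample band into a cross-blot-comparable amount.

    Lanes whose back-calculated amount is nonpositive are excluded and logged
    (flooring them would fabricate signal that biases the log-ratios).
    Returns columns blot_id, sample_id, tissue, analyte, fraction, amount,
    extrapolated.
    """
    curves = fit_all_curves(lanes, through_origin=through_origin)
    rows, dropped = [], 0
    samples = lanes[lanes["fraction"] != "std"]
    for rec in samples.itertuples(index=False):
        curve = curves.get((rec.blot_id, rec.analyte))
        if curve is None:
            raise InsufficientStandardsError(
                f"no standard curve for blot {rec.blot_id}, analyte {rec.analyte}")
        try:
            amount, extrapolated = curve.quantify(float(rec.intensity))
        except NonpositiveAmountError as exc:
            dropped += 1
            log.warning("excluding lane (%s, %s): %s", rec.blot_id, rec.lane_index, exc)
            continue
        rows.append((rec.blot_id, rec.sample_id, rec.tissue, rec.analyte,
                     rec.fraction, amount, extrapolated))
    if dropped:
        log.warning("calibrate_lanes: excluded %d nonpositive-amount lanes", dropped)
    return pd.DataFrame(rows, columns=["blot_id", "sample_id", "tissue", "analyte",
                                       "fraction", "amount", "extrapolated"])


def marker_normalize(amounts: pd.DataFrame) -> pd.DataFrame:
    """Relative mitochondrial / cytosolic protein per sample and analyte.

    rel_mito = amount(analyte, mito) / amount(COX IV, mito) and
    rel_cyto = amount(analyte, cyto) / amount(beta-ACTIN, cyto), markers taken
    from the same sample's fractionation lanes, which cancels fraction
    loading.  Returns columns sample_id, tissue, analyte, rel_mito, rel_cyto.
    """
    rows = []
    frac = amounts[amounts["fraction"].isin(["mito", "cyto"])]
    for sid, grp in frac.groupby("sample_id", sort=True):
        tissue = grp["tissue"].iloc[0]
        by_key = {(r.analyte, r.fraction): r.amount for r in grp.itertuples(index=False)}
        for marker, fraction in ((MITO_MARKER, "mito"), (CYTO_MARKER, "cyto")):
            if (marker, fraction) not in by_key:
                raise MissingMarkerError(
                    f"sample {sid}: missing {marker} band in {fraction} fraction")
        for analyte in sorted({a for a, _ in by_key} - {MITO_MARKER, CYTO_MARKER}):
            amt_mito = by_key.get((analyte, "mito"))
            amt_cyto = by_key.get((analyte, "cyto"))
            if amt_mito is None or amt_cyto is None:
                log.warning("sample %s: %s lacks a %s band (excluded upstream); "
                            "skipping", sid, analyte,
                            "mito" if amt_mito is None else "cyto")
                continue
            rows.append((sid, tissue, analyte,
                         amt_mito / by_key[(MITO_MARKER, "mito")],
                         amt_cyto / by_key[(CYTO_MARKER, "cyto")]))
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "analyte",
                                       "rel_mito", "rel_cyto"])


def read_lane_table(path) -> pd.DataFrame:
    """Read a lane TSV (schema: blot_id, lane_index, analyte, fraction,
    sample_id, tissue, std_amount, intensity)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    df["sample_id"] = df["sample_id"].fillna("")
    return df


def write_lane_table(lanes: pd.DataFrame, path) -> None:
    lanes.to_csv(path, sep="\t", index=False, float_format="%.10g")
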