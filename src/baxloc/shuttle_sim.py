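"""Synthetic cohort generator: shuttling kinetics, blot rendering, expression and survival.

The generator emulates the measurement chain of a fractionation western-blot
study of BAX/BAK localization in paired tumor / non-tumor tissue:

* per-patient ground-truth localization arises from a memoryless
  two-compartment exchange (translocation to the mitochondria at rate
  ``k_trans``, retrotranslocation to the cytosol at rate ``k_retro``) at
  steady state;
* a planted "BAX-protected" subgroup carries a fold-increase of tumor BAX
  retrotranslocation, shifting BAX to the cytosol by
  ``log10(protected_retro_fold)`` (~2 log10 units at the default fold of 100);
* blots are rendered band-by-band with per-blot x per-analyte gain, a HeLa
  whole-cell-lysate titration (standard curve) on every blot, fraction
  loading controls (COX IV for mitochondria, beta-ACTIN for cytosol), and
  multiplicative lognormal densitometry noise;
* matched expression matrices (log2 intensities, detection-failure mask) and
  survival tables (exponential event times, independent exponential
  censoring) are emitted for the downstream signature and survival stages.

The protected flag is hidden ground truth: rendered lane tables never carry
it, so the classifier cannot leak it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidParameterError
from .omics_stats import ExpressionMatrix
from .survival import SurvivalRecord

ANALYTES = ("BAX", "BAK")
MITO_MARKER = "COXIV"
CYTO_MARKER = "ACTIN"
ALL_ANALYTES = ANALYTES + (MITO_MARKER, CYTO_MARKER)

#: lane-table schema shared with blot_quant
LANE_COLUMNS = (
    "blot_id",
    "lane_index",
    "analyte",
    "fraction",
    "sample_id",
    "tissue",
    "std_amount",
    "intensity",
)


@dataclass(frozen=True)
class ShuttleParams:
    """Two-compartment shuttling rates and total abundance for one analyte.

    Rates are per hour; ``total_protein`` is in HeLa-equivalent units (amount
    relative to the per-blot HeLa lysate titration standard).
    """

    k_trans: float
    k_retro: float
    total_protein: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_trans", "k_retro", "total_protein"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")


def steady_state_fraction(params: ShuttleParams) -> float:
    """Mitochondrial fraction at steady state, ``k_trans / (k_trans + k_retro)``.

    Strictly increasing in ``k_trans`` and strictly decreasing in ``k_retro``;
    multiplied by ``total_protein`` it gives the mitochondrial amount.
    """
    return params.k_trans / (params.k_trans + params.k_retro)


@dataclass(frozen=True)
class TissueTruth:
    """Ground-truth state of one tissue sample (one patient, tumor or non-tumor)."""

    patient_id: str
    tissue: str  # "tumor" | "non_tumor"
    params: Mapping[str, ShuttleParams]  # per analyte (BAX, BAK)
    coxiv_amount: float
    actin_amount: float
    omm_integral_fraction: float = 0.2  # carbonate pellet share of the mito pool

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}_{'T' if self.tissue == 'tumor' else 'N'}"

    @property
    def tissue_code(self) -> str:
        return "T" if self.tissue == "tumor" else "N"

    def mito_amount(self, analyte: str) -> float:
        p = self.params[analyte]
        return p.total_protein * steady_state_fraction(p)

    def cyto_amount(self, analyte: str) -> float:
        p = self.params[analyte]
        return p.total_protein - self.mito_amount(analyte)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort, noise and blot-layout settings.

    The defaults are the packaged "study_cohort" configuration: a 34-patient
    paired cohort with 11 protected patients whose tumor BAX retrotranslocation
    is accelerated 100-fold (a 2-log10 cytosolic shift), rendered at realistic
    densitometry noise with a five-point HeLa titration on every blot.
    """

    n_patients: int = 34
    fraction_protected: float = 11 / 34
    protected_retro_fold: float = 100.0
    lanes_per_blot: int = 50
    noise_sd_log10: float = 0.15
    gain_sd_log10: float = 0.3
    loading_sd_log10: float = 0.2
    rate_jitter_log10: float = 0.05
    retro_spread_log10: float = 0.5
    abundance_sd_log10: float = 0.2
    #: markers are loading controls, stable by construction of the assay
    marker_sd_log10: float = 0.05
    standard_amounts: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    include_carbonate: bool = False
    carbonate_integral_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 <= self.fraction_protected <= 1.0:
            raise ConfigurationError("fraction_protected must lie in [0, 1]")
        if self.protected_retro_fold < 1.0:
            raise ConfigurationError("protected_retro_fold must be >= 1")
        for name in ("noise_sd_log10", "gain_sd_log10", "loading_sd_log10",
                     "rate_jitter_log10", "retro_spread_log10",
                     "abundance_sd_log10", "marker_sd_log10"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        amounts = tuple(self.standard_amounts)
        if len(amounts) < 3 or any(b <= a for a, b in zip(amounts, amounts[1:])):
            raise ConfigurationError(
                "standard_amounts must be strictly increasing with >= 3 points")
        if amounts[0] <= 0:
            raise ConfigurationError("standard_amounts must be positive")
        if not 0.0 < self.carbonate_integral_fraction < 1.0:
            raise ConfigurationError("carbonate_integral_fraction must lie in (0, 1)")


def study_cohort(**overrides) -> CohortConfig:
    """The default study-scale configuration; keyword overrides allowed."""
    return replace(CohortConfig(), **overrides) if overrides else CohortConfig()


@dataclass(frozen=True)
class CohortTruth:
    """Paired ground truth for a simulated cohort.

    ``protected_ids`` is hidden evaluation-only truth: it is never written to
    lane tables and must not be read by any scoring or classification stage.
    """

    tissues: tuple[TissueTruth, ...]
    protected_ids: frozenset[str]
    config: CohortConfig = field(repr=False, default=None)

    @property
    def patient_ids(self) -> list[str]:
        seen: list[str] = []
        for t in self.tissues:
            if t.patient_id not in seen:
                seen.append(t.patient_id)
        return seen

    def pair(self, patient_id: str) -> tuple[TissueTruth, TissueTruth]:
        """(tumor, non_tumor) truth for one patient."""
        tum = next(t for t in self.tissues
                   if t.patient_id == patient_id and t.tissue == "tumor")
        non = next(t for t in self.tissues
                   if t.patient_id == patient_id and t.tissue == "non_tumor")
        return tum, non


def simulate_cohort(config: CohortConfig) -> CohortTruth:
    """Draw paired tumor / non-tumor ground truth for ``config.n_patients`` patients.

    Exactly ``round(fraction_protected * n)`` patients are flagged protected;
    their tumor BAX ``k_retro`` is the non-tumor rate times
    ``protected_retro_fold`` (up to the per-tissue rate jitter). BAK rates and
    all non-protected BAX rates differ between tissues only by jitter.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_patients
    n_prot = int(round(config.fraction_protected * n))
    prot_idx = set(rng.choice(n, size=n_prot, replace=False).tolist())

    tissues: list[TissueTruth] = []
    protected: set[str] = set()
    for i in range(n):
        pid = f"P{i + 1:02d}"
        is_prot = i in prot_idx
        if is_prot:
            protected.add(pid)
        # non-tumor baseline: BAX and BAK retrotranslocate at similar,
        # strongly correlated rates (the cohort-wide spread sets the Fig-1-like
        # geometry of localization values across patients)
        base_bax = 0.5 + config.retro_spread_log10 * rng.standard_normal()
        base_bak = base_bax + 0.15 * rng.standard_normal()
        jit = lambda: config.rate_jitter_log10 * rng.standard_normal()
        log_kr = {
            ("non_tumor", "BAX"): base_bax,
            ("non_tumor", "BAK"): base_bak,
            ("tumor", "BAX"): base_bax + jit()
            + (math.log10(config.protected_retro_fold) if is_prot else 0.0),
            ("tumor", "BAK"): base_bak + jit(),
        }
        for tissue in ("non_tumor", "tumor"):
            params = {
                an: ShuttleParams(
                    k_trans=1.0,
                    k_retro=10.0 ** log_kr[(tissue, an)],
                    total_protein=10.0 ** (config.abundance_sd_log10
                                           * rng.standard_normal()),
                )
                for an in ANALYTES
            }
            tissues.append(TissueTruth(
                patient_id=pid,
                tissue=tissue,
                params=params,
                coxiv_amount=10.0 ** (config.marker_sd_log10 * rng.standard_normal()),
                actin_amount=10.0 ** (config.marker_sd_log10 * rng.standard_normal()),
                omm_integral_fraction=config.carbonate_integral_fraction,
            ))
    return CohortTruth(tissues=tuple(tissues), protected_ids=frozenset(protected),
                       config=config)


def _sample_bands(truth: TissueTruth, include_carbonate: bool):
    """(analyte, fraction, amount-key) bands rendered for one sample lane block."""
    bands = [
        ("BAX", "mito", truth.mito_amount("BAX")),
        ("BAK", "mito", truth.mito_amount("BAK")),
        (MITO_MARKER, "mito", truth.coxiv_amount),
        ("BAX", "cyto", truth.cyto_amount("BAX")),
        ("BAK", "cyto", truth.cyto_amount("BAK")),
        (CYTO_MARKER, "cyto", truth.actin_amount),
    ]
    if include_carbonate:
        mito_bax = truth.mito_amount("BAX")
        bands += [
            ("BAX", "carb_pellet", truth.omm_integral_fraction * mito_bax),
            ("BAX", "carb_sup", (1.0 - truth.omm_integral_fraction) * mito_bax),
        ]
    return bands


def render_blots(truths: Sequence[TissueTruth], config: CohortConfig) -> pd.DataFrame:
    """Render ground truth as a noisy band-level lane table.

    Every blot carries the full HeLa titration for each probed analyte plus
    up to ``lanes_per_blot`` band lanes in total.  Band intensity is
    ``gain(blot, analyte) * loaded_amount * 10**N(0, noise_sd_log10)`` with the
    gain drawn per blot and analyte and a shared loading factor per sample and
    fraction group (so loading cancels in marker normalization).  A patient's
    tissues are never split across blots, so paired tumor / non-tumor
    comparisons share one calibration (the convention for paired samples).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_std = len(ALL_ANALYTES) * len(config.standard_amounts)
    per_sample = len(_sample_bands(truths[0], config.include_carbonate)) if truths else 6

    # group consecutive tissues of one patient, then pack whole groups
    groups: list[list[TissueTruth]] = []
    for t in truths:
        if groups and groups[-1][0].patient_id == t.patient_id:
            groups[-1].append(t)
        else:
            groups.append([t])
    max_group = max((len(g) for g in groups), default=1)
    if config.lanes_per_blot < n_std + max_group * per_sample:
        raise ConfigurationError(
            f"lanes_per_blot={config.lanes_per_blot} cannot hold the titration "
            f"({n_std} lanes) plus one patient ({max_group * per_sample} lanes)")
    capacity = config.lanes_per_blot - n_std
    blots: list[list[TissueTruth]] = [[]]
    for g in groups:
        if (len(blots[-1]) + len(g)) * per_sample > capacity:
            blots.append([])
        blots[-1].extend(g)

    blots = [b for b in blots if b]
    rows: list[tuple] = []
    for bi, blot_samples in enumerate(blots):
        blot_id = f"B{bi + 1:02d}"
        gain = {an: 10.0 ** (config.gain_sd_log10 * rng.standard_normal())
                for an in ALL_ANALYTES}
        noise = lambda: 10.0 ** (config.noise_sd_log10 * rng.standard_normal())
        lane = 0
        for an in ALL_ANALYTES:
            for amt in config.standard_amounts:
                lane += 1
                rows.append((blot_id, lane, an, "std", "", "NA", amt,
                             gain[an] * amt * noise()))
        for truth in blot_samples:
            loading = {
                "mito": 10.0 ** (config.loading_sd_log10 * rng.standard_normal()),
                "cyto": 10.0 ** (config.loading_sd_log10 * rng.standard_normal()),
                "carb": 10.0 ** (config.loading_sd_log10 * rng.standard_normal()),
            }
            for an, fraction, amount in _sample_bands(truth, config.include_carbonate):
                lane += 1
                load = loading["carb" if fraction.startswith("carb") else fraction]
                rows.append((blot_id, lane, an, fraction, truth.sample_id,
                             truth.tissue_code, np.nan, gain[an] * amount * load * noise()))
    return pd.DataFrame(rows, columns=list(LANE_COLUMNS))


def simulate_expression(
    labels: Sequence,
    n_genes: int = 2000,
    n_de: int = 50,
    effect_log2: float = 2.0,
    sd_log2: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Expression matrix (log2 intensities) with planted group effects.

    The first ``n_de`` genes differ in mean by ``effect_log2`` between the two
    label classes (alternating sign); missingness is injected completely at
    random at ``missing_rate`` and recorded in the detection-failure mask.
    Returns the matrix and the planted differential gene ids (hidden truth).
    """
    labels = list(labels)
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise ConfigurationError(f"labels must define exactly 2 classes, got {classes}")
    if not 0 <= n_de <= n_genes:
        raise ConfigurationError("n_de must lie in [0, n_genes]")
    if not 0.0 <= missing_rate < 1.0:
        raise ConfigurationError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng([seed, 3])
    n_samples = len(labels)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]

    base = 8.0 + 1.5 * rng.standard_normal(n_genes)
    values = base[:, None] + sd_log2 * rng.standard_normal((n_genes, n_samples))
    in_class1 = np.array([lab == classes[1] for lab in labels])
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    values[:n_de, :] += np.outer(signs * effect_log2, in_class1.astype(float))
    mask = rng.random((n_genes, n_samples)) < missing_rate

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=list(sample_ids)),
        mask=pd.DataFrame(mask, index=gene_ids, columns=list(sample_ids)),
    )
    return matrix, gene_ids[:n_de]


def simulate_survival(
    labels: Mapping[str, object] | Sequence,
    hazard_ratio: float = 1.0,
    baseline_rate: float = 1.0 / 1000.0,
    censor_rate: float = 0.0,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> list[SurvivalRecord]:
    """Exponential event times with subgroup-dependent hazard.

    Samples in the lexicographically higher label class have hazard
    ``baseline_rate * hazard_ratio`` (per day); censoring is an independent
    exponential at ``censor_rate`` (0 disables censoring, so every event is
    observed).
    """
    if isinstance(labels, Mapping):
        sample_ids = list(labels.keys())
        labels = list(labels.values())
    else:
        labels = list(labels)
        if sample_ids is None:
            sample_ids = [f"S{i + 1:03d}" for i in range(len(labels))]
    if hazard_ratio <= 0 or baseline_rate <= 0 or censor_rate < 0:
        raise ConfigurationError("rates must be positive (censor_rate >= 0)")
    classes = sorted(set(labels), key=str)
    high = classes[-1]
    rng = np.random.default_rng([seed, 4])
    records = []
    for sid, lab in zip(sample_ids, labels):
        rate = baseline_rate * (hazard_ratio if lab == high else 1.0)
        t_event = rng.exponential(1.0 / rate)
        if censor_rate > 0:
            t_cens = rng.exponential(1.0 / censor_rate)
        else:
            t_cens = np.inf
        records.append(SurvivalRecord(
            sample_id=sid,
            time=float(min(t_event, t_cens)),
            event=int(t_event <= t_cens),
            stratum=str(lab),
        ))
    return records
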