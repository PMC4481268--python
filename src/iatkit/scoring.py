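"""IAT score formulas (Parameter 3), practice/test pooling (Parameter 4),
algorithm enumeration and the named presets.

An algorithm is a 4-tuple of option codes (latency treatment, error
treatment, score formula, phase pooling) with canonical id
``P1.x-P2.y-P3.z-P4.w`` where x..w are the option numbers of Table-style
parameter listings (P1: 1 none .. 6 inverse trim; P2: 1 ignore, 2 exclude,
3 recode 2SD, 4 separate, 5 recode 600; P3: 1 D .. 7 inverse-trimmed mini
differences; P4: 1 no distinction, 2 distinction).

The full cross is 6 x 5 x 7 x 2 = 420 algorithms. Ignore and Separate are
provably identical whenever the latency treatment does not depend on the
latency distribution (none, fixed trimming, fixed winsorizing), so the
deduplicated set has 420 - 3*7*2 = 378 unique algorithms.

Sign convention: positive scores mean slower responding in the incompatible
pairing, i.e. a target-consistent implicit preference.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pretreatment import (
    DISTRIBUTION_BASED,
    ERROR_OPTIONS,
    ERROR_OPTION_NUMBER,
    LATENCY_OPTIONS,
    LATENCY_OPTION_NUMBER,
    ErrorTreatmentOption,
    LatencyTreatmentOption,
    apply_error_treatment,
    apply_latency_treatment,
)
from .trialdata import PAIRINGS, PHASES, TrialTable

FORMULAS = ("D", "G", "WPR", "MD", "MD_trim", "MD_winsor", "MD_inverse_trim")
FORMULA_NUMBER = {code: i + 1 for i, code in enumerate(FORMULAS)}
PHASE_OPTIONS = ("no_distinction", "distinction")
PHASE_OPTION_NUMBER = {code: i + 1 for i, code in enumerate(PHASE_OPTIONS)}

#: minimum scored latencies a block (or phase subset) must retain
MIN_BLOCK_N = 2

_MINIDIFF_TREATMENT = {
    "plain": "none",
    "trim": "stat_trim",
    "winsor": "stat_winsor",
    "inverse_trim": "stat_inverse_trim",
}


class ScoreUndefined(Exception):
    """A score could not be computed; ``.reason`` carries a stable code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True, order=True)
class AlgorithmSpec:
    """One scoring algorithm: a choice for each of the four parameters."""

    p1: str = "none"
    p2: str = "ignore"
    p3: str = "D"
    p4: str = "no_distinction"

    def __post_init__(self) -> None:
        for value, valid, name in (
            (self.p1, LATENCY_OPTIONS, "p1"),
            (self.p2, ERROR_OPTIONS, "p2"),
            (self.p3, FORMULAS, "p3"),
            (self.p4, PHASE_OPTIONS, "p4"),
        ):
            if value not in valid:
                raise ValueError(f"invalid {name}={value!r}; valid: {valid}")

    @property
    def algorithm_id(self) -> str:
        return (
            f"P1.{LATENCY_OPTION_NUMBER[self.p1]}"
            f"-P2.{ERROR_OPTION_NUMBER[self.p2]}"
            f"-P3.{FORMULA_NUMBER[self.p3]}"
            f"-P4.{PHASE_OPTION_NUMBER[self.p4]}"
        )

    @classmethod
    def from_id(cls, algorithm_id: str) -> "AlgorithmSpec":
        try:
            parts = dict(p.split(".") for p in algorithm_id.split("-"))
            return cls(
                p1=LATENCY_OPTIONS[int(parts["P1"]) - 1],
                p2=ERROR_OPTIONS[int(parts["P2"]) - 1],
                p3=FORMULAS[int(parts["P3"]) - 1],
                p4=PHASE_OPTIONS[int(parts["P4"]) - 1],
            )
        except (KeyError, IndexError, ValueError) as exc:
            raise ValueError(f"malformed algorithm id {algorithm_id!r}") from exc

    def options(self) -> tuple[LatencyTreatmentOption, ErrorTreatmentOption]:
        return LatencyTreatmentOption(self.p1), ErrorTreatmentOption(self.p2)


# ---------------------------------------------------------------------------
# Parameter-3 formulas. Each takes the treated latency vectors of the two
# critical blocks and raises ScoreUndefined on degenerate input.
# ---------------------------------------------------------------------------

def _check_min_n(compatible: np.ndarray, incompatible: np.ndarray) -> None:
    if len(compatible) < MIN_BLOCK_N or len(incompatible) < MIN_BLOCK_N:
        raise ScoreUndefined("too_few_trials")


def score_d(compatible: np.ndarray, incompatible: np.ndarray) -> float:
    """D: block mean difference over the SD of all latencies in both blocks."""
    compatible = np.asarray(compatible, float)
    incompatible = np.asarray(incompatible, float)
    _check_min_n(compatible, incompatible)
    pooled_sd = float(np.std(np.concatenate([compatible, incompatible]), ddof=1))
    if pooled_sd == 0:
        raise ScoreUndefined("zero_pooled_sd")
    return float((incompatible.mean() - compatible.mean()) / pooled_sd)


def gaussian_ranks(values: np.ndarray) -> np.ndarray:
    """Normal quantiles of fractional midranks, (rank - 0.5) / N.

    This convention is the single place the G score's rank definition lives.
    """
    values = np.asarray(values, float)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


def score_g(compatible: np.ndarray, incompatible: np.ndarray) -> float:
    """G: difference of block means after transforming the pooled latencies
    to Gaussian ranks. Scale-free and monotone-invariant."""
    compatible = np.asarray(compatible, float)
    incompatible = np.asarray(incompatible, float)
    _check_min_n(compatible, incompatible)
    z = gaussian_ranks(np.concatenate([compatible, incompatible]))
    n_c = compatible.size
    return float(z[n_c:].mean() - z[:n_c].mean())


def score_wpr(compatible: np.ndarray, incompatible: np.ndarray) -> float:
    """Worst Performance Rule: difference of the blocks' 90th percentiles
    over the pooled SD. Quantiles by linear order-statistic interpolation."""
    compatible = np.asarray(compatible, float)
    incompatible = np.asarray(incompatible, float)
    _check_min_n(compatible, incompatible)
    pooled_sd = float(np.std(np.concatenate([compatible, incompatible]), ddof=1))
    if pooled_sd == 0:
        raise ScoreUndefined("zero_pooled_sd")
    q_i = float(np.quantile(incompatible, 0.90))
    q_c = float(np.quantile(compatible, 0.90))
    return float((q_i - q_c) / pooled_sd)


def minidiffs(compatible: np.ndarray, incompatible: np.ndarray) -> np.ndarray:
    """All pairwise incompatible-minus-compatible latency differences."""
    return np.subtract.outer(
        np.asarray(incompatible, float), np.asarray(compatible, float)
    ).ravel()


def score_minidiff(
    compatible: np.ndarray,
    incompatible: np.ndarray,
    variant: str = "plain",
    proportion: float = 0.10,
) -> float:
    """Mini differences: mean over SD of all pairwise block differences.

    ``variant`` optionally trims / winsorizes / inverse-trims the difference
    distribution (the same statistical operators as Parameter 1) before the
    mean and SD are taken — both on the treated set.
    """
    if variant not in _MINIDIFF_TREATMENT:
        raise ValueError(f"unknown mini-difference variant {variant!r}")
    compatible = np.asarray(compatible, float)
    incompatible = np.asarray(incompatible, float)
    _check_min_n(compatible, incompatible)
    d = minidiffs(compatible, incompatible)
    opt = LatencyTreatmentOption(_MINIDIFF_TREATMENT[variant], proportion=proportion)
    treated = apply_latency_treatment(d, opt).latencies
    if treated.size < 2:
        raise ScoreUndefined("too_few_differences")
    sd = float(np.std(treated, ddof=1))
    if sd == 0:
        raise ScoreUndefined("zero_difference_sd")
    return float(np.mean(treated) / sd)


_FORMULA_FUNCS = {
    "D": score_d,
    "G": score_g,
    "WPR": score_wpr,
    "MD": lambda c, i: score_minidiff(c, i, "plain"),
    "MD_trim": lambda c, i: score_minidiff(c, i, "trim"),
    "MD_winsor": lambda c, i: score_minidiff(c, i, "winsor"),
    "MD_inverse_trim": lambda c, i: score_minidiff(c, i, "inverse_trim"),
}


# ---------------------------------------------------------------------------
# Subject-level pipeline
# ---------------------------------------------------------------------------

BlockArrays = Mapping[tuple[str, str], tuple[np.ndarray, np.ndarray]]
"""(pairing, phase) -> (latency vector, error-flag vector), in trial order."""


def _gather_blocks(trials: pd.DataFrame) -> dict:
    out = {}
    for (pairing, phase), sub in trials.groupby(["pairing", "phase"], observed=False):
        out[(pairing, phase)] = (
            sub["latency_ms"].to_numpy(float),
            sub["error"].to_numpy(bool),
        )
    return out


def _pool_phases(blocks: BlockArrays, pairing: str) -> tuple[np.ndarray, np.ndarray]:
    lats, errs = [], []
    for phase in PHASES:
        if (pairing, phase) in blocks:
            lat, err = blocks[(pairing, phase)]
            lats.append(lat)
            errs.append(err)
    if not lats:
        return np.empty(0), np.empty(0, bool)
    return np.concatenate(lats), np.concatenate(errs)


def _treated_pair(
    blocks: BlockArrays,
    spec: AlgorithmSpec,
    phase: str | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Treated (compatible, incompatible) vectors for one scoring unit."""
    l_opt, e_opt = LatencyTreatmentOption(spec.p1), ErrorTreatmentOption(spec.p2)
    treated = {}
    for pairing in PAIRINGS:
        if phase is None:
            lat, err = _pool_phases(blocks, pairing)
        else:
            lat, err = blocks.get((pairing, phase), (np.empty(0), np.empty(0, bool)))
        block = apply_error_treatment(lat, err, e_opt, l_opt)
        if block.bookkeeping.degenerate:
            raise ScoreUndefined(block.bookkeeping.reason or "degenerate_block")
        treated[pairing] = block.latencies
    return treated["compatible"], treated["incompatible"]


def score_subject(trials: pd.DataFrame, spec: AlgorithmSpec) -> float:
    """Score one subject's critical trials under one algorithm.

    ``trials`` is that subject's slice of a TrialTable (one session). Raises
    :class:`ScoreUndefined` on degenerate input (too few trials after the
    treatments, zero variability, or a missing phase under Distinction).
    """
    blocks = _gather_blocks(trials)
    formula = _FORMULA_FUNCS[spec.p3]
    if spec.p4 == "no_distinction":
        comp, incomp = _treated_pair(blocks, spec, None)
        return formula(comp, incomp)
    phase_scores = []
    for phase in PHASES:
        comp, incomp = _treated_pair(blocks, spec, phase)
        phase_scores.append(formula(comp, incomp))
    return float(np.mean(phase_scores))


# ---------------------------------------------------------------------------
# ScoreMatrix: subjects x algorithms
# ---------------------------------------------------------------------------

@dataclass
class ScoreMatrix:
    """Subject-by-algorithm score table with missingness bookkeeping.

    ``scores`` has subject ids as index and canonical algorithm ids as
    columns; missing cells are NaN with the reason code recorded in
    ``missing_reasons[(subject, algorithm_id)]``.
    """

    scores: pd.DataFrame
    missing_reasons: dict

    def column(self, spec_or_id) -> pd.Series:
        key = getattr(spec_or_id, "algorithm_id", spec_or_id)
        return self.scores[key]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.scores.rename_axis("subject").to_csv(path)
        sidecar = {
            f"{s}|{a}": reason for (s, a), reason in self.missing_reasons.items()
        }
        path.with_suffix(".meta.json").write_text(
            json.dumps({"missing_reasons": sidecar}, indent=2)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreMatrix":
        path = Path(path)
        df = pd.read_csv(path).set_index("subject")
        reasons = {}
        meta = path.with_suffix(".meta.json")
        if meta.exists():
            raw = json.loads(meta.read_text()).get("missing_reasons", {})
            for key, reason in raw.items():
                subj, alg = key.split("|", 1)
                reasons[(subj, alg)] = reason
        return cls(df, reasons)


def score_table(
    table: TrialTable,
    specs: Sequence[AlgorithmSpec],
    session: int | None = None,
) -> ScoreMatrix:
    """Score every subject under every algorithm.

    Treated latency sets are shared across the seven formulas of a common
    (latency, error, phase) treatment combination, so the full 420-algorithm
    cross costs only 6 x 5 x 2 pretreatment passes per subject.
    """
    trials = table.trials
    if session is not None:
        trials = trials[trials["session"] == session]
    elif "session" in trials.columns:
        first = min(table.sessions)
        trials = trials[trials["session"] == first]

    specs = list(specs)
    by_treatment: dict[tuple[str, str, str], list[AlgorithmSpec]] = {}
    for spec in specs:
        by_treatment.setdefault((spec.p1, spec.p2, spec.p4), []).append(spec)

    subjects = sorted(trials["subject"].unique().tolist())
    values = {spec.algorithm_id: [] for spec in specs}
    reasons: dict = {}

    for subject in subjects:
        blocks = _gather_blocks(trials[trials["subject"] == subject])
        for (p1, p2, p4), members in by_treatment.items():
            probe = AlgorithmSpec(p1, p2, "D", p4)
            pairs: list[tuple[np.ndarray, np.ndarray]] | None
            try:
                if p4 == "no_distinction":
                    pairs = [_treated_pair(blocks, probe, None)]
                else:
                    pairs = [_treated_pair(blocks, probe, ph) for ph in PHASES]
                failure = None
            except ScoreUndefined as exc:
                pairs, failure = None, exc.reason
            for spec in members:
                if pairs is None:
                    values[spec.algorithm_id].append(np.nan)
                    reasons[(subject, spec.algorithm_id)] = failure
                    continue
                try:
                    formula = _FORMULA_FUNCS[spec.p3]
                    score = float(np.mean([formula(c, i) for c, i in pairs]))
                    values[spec.algorithm_id].append(score)
                except ScoreUndefined as exc:
                    values[spec.algorithm_id].append(np.nan)
                    reasons[(subject, spec.algorithm_id)] = exc.reason
    df = pd.DataFrame(values, index=pd.Index(subjects, name="subject"))
    return ScoreMatrix(df, reasons)


# ---------------------------------------------------------------------------
# Enumeration, deduplication, presets
# ---------------------------------------------------------------------------

def is_duplicate_pair(spec: AlgorithmSpec) -> bool:
    """True when the spec is the Separate twin of an identical Ignore spec
    (latency treatment not distribution-based)."""
    return spec.p2 == "separate" and spec.p1 not in DISTRIBUTION_BASED


def enumerate_algorithms(deduplicate: bool = False) -> list[AlgorithmSpec]:
    """All 420 algorithm specs in deterministic (option-number) order, or
    the 378 unique ones when ``deduplicate`` is true (the Ignore-coded spec
    is kept as the canonical representative of each merged pair)."""
    specs = [
        AlgorithmSpec(p1, p2, p3, p4)
        for p1, p2, p3, p4 in itertools.product(
            LATENCY_OPTIONS, ERROR_OPTIONS, FORMULAS, PHASE_OPTIONS
        )
    ]
    if deduplicate:
        specs = [s for s in specs if not is_duplicate_pair(s)]
    return specs


_PRESETS = {
    "D2": AlgorithmSpec("fixed_trim", "ignore", "D", "distinction"),
    "D5": AlgorithmSpec("fixed_trim", "recode_2sd", "D", "distinction"),
    "D6": AlgorithmSpec("fixed_trim", "recode_600", "D", "distinction"),
    "G_standard": AlgorithmSpec("none", "ignore", "G", "no_distinction"),
    "D2_improved": AlgorithmSpec("stat_winsor", "ignore", "D", "no_distinction"),
    "D5_improved": AlgorithmSpec("stat_winsor", "recode_2sd", "D", "no_distinction"),
    "D6_improved": AlgorithmSpec("stat_winsor", "recode_600", "D", "no_distinction"),
}


def preset(name: str) -> AlgorithmSpec:
    """Named algorithm presets.

    D2/D5/D6 are the classic scores (fixed-value trimming, Distinction, with
    errors ignored / recoded to mean+2SD / recoded to mean+600 respectively).
    The improved variants swap in statistical winsorizing and drop the
    practice/test distinction. G_standard is the plain Gaussian-rank score.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid: {sorted(_PRESETS)}"
        ) from None


def preset_names() -> list[str]:
    return sorted(_PRESETS)
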