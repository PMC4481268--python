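"""Extreme-latency treatment (Parameter 1) and error treatment (Parameter 2).

Both operate within one critical block (a latency vector, or a latency +
error-flag pair of vectors). Latencies above the global 10 s ceiling are
removed unconditionally, for correct and error trials alike, before any
option-specific treatment.

Latency treatment options
-------------------------
``none``              no treatment (baseline)
``fixed_trim``        eliminate latencies < 400 ms
``fixed_winsor``      recode latencies < 300 ms to 300 and > 3000 ms to 3000
``stat_trim``         remove the k = floor(p*n) fastest and k slowest
``stat_winsor``       replace those 2k values by the nearest retained order
                      statistics
``stat_inverse_trim`` remove the k values immediately below and the k
                      immediately above the median

Error treatment options
-----------------------
``ignore``      pool correct and error latencies, then latency-treat the pool
``exclude``     drop error latencies; latency-treat correct only
``separate``    latency-treat the correct and the error subset independently
``recode_2sd``  latency-treat correct; each error -> mean + 2*SD of the
                treated correct latencies
``recode_600``  as above with a fixed 600 ms penalty

Recoded error latencies are not re-subjected to the latency treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CEILING_MS = 10_000.0

LATENCY_OPTIONS = (
    "none",
    "fixed_trim",
    "fixed_winsor",
    "stat_trim",
    "stat_winsor",
    "stat_inverse_trim",
)
ERROR_OPTIONS = ("ignore", "exclude", "recode_2sd", "separate", "recode_600")

#: option codes -> the numbers used in canonical algorithm ids
LATENCY_OPTION_NUMBER = {code: i + 1 for i, code in enumerate(LATENCY_OPTIONS)}
ERROR_OPTION_NUMBER = {code: i + 1 for i, code in enumerate(ERROR_OPTIONS)}

#: distribution-dependent latency options (Ignore and Separate differ only here)
DISTRIBUTION_BASED = frozenset({"stat_trim", "stat_winsor", "stat_inverse_trim"})


@dataclass(frozen=True)
class LatencyTreatmentOption:
    """Parameter-1 option with its numeric constants."""

    code: str = "none"
    proportion: float = 0.10
    fixed_trim_lower: float = 400.0
    winsor_lower: float = 300.0
    winsor_upper: float = 3000.0

    def __post_init__(self) -> None:
        if self.code not in LATENCY_OPTIONS:
            raise ValueError(f"unknown latency option {self.code!r}; valid: {LATENCY_OPTIONS}")
        if not 0 <= self.proportion < 0.5:
            raise ValueError("proportion must be in [0, 0.5)")
        if not 0 < self.winsor_lower < self.winsor_upper:
            raise ValueError("winsor bounds must be positive and ordered")


@dataclass(frozen=True)
class ErrorTreatmentOption:
    """Parameter-2 option with its penalty constants."""

    code: str = "ignore"
    penalty_ms: float = 600.0
    penalty_sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.code not in ERROR_OPTIONS:
            raise ValueError(f"unknown error option {self.code!r}; valid: {ERROR_OPTIONS}")


@dataclass
class Bookkeeping:
    """Per-block treatment accounting.

    Invariant: n_input == n_scored + n_over_ceiling + n_treatment_removed
    + n_errors_excluded.
    """

    n_input: int = 0
    n_scored: int = 0
    n_over_ceiling: int = 0
    n_treatment_removed: int = 0
    n_winsorized: int = 0
    n_errors_excluded: int = 0
    n_errors_recoded: int = 0
    degenerate: bool = False
    reason: Optional[str] = None

    def merge(self, other: "Bookkeeping") -> "Bookkeeping":
        return Bookkeeping(
            n_input=self.n_input + other.n_input,
            n_scored=self.n_scored + other.n_scored,
            n_over_ceiling=self.n_over_ceiling + other.n_over_ceiling,
            n_treatment_removed=self.n_treatment_removed + other.n_treatment_removed,
            n_winsorized=self.n_winsorized + other.n_winsorized,
            n_errors_excluded=self.n_errors_excluded + other.n_errors_excluded,
            n_errors_recoded=self.n_errors_recoded + other.n_errors_recoded,
            degenerate=self.degenerate or other.degenerate,
            reason=self.reason or other.reason,
        )


@dataclass
class TreatedBlock:
    """Scored latencies of one critical block plus bookkeeping."""

    latencies: np.ndarray
    bookkeeping: Bookkeeping = field(default_factory=Bookkeeping)


def remove_ceiling(latencies: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop latencies above the 10 s ceiling; returns (kept, n_removed)."""
    latencies = np.asarray(latencies, dtype=float)
    keep = latencies <= CEILING_MS
    return latencies[keep], int((~keep).sum())


def _tail_k(n: int, proportion: float) -> int:
    return int(np.floor(proportion * n))


def apply_latency_treatment(
    latencies: np.ndarray, option: LatencyTreatmentOption
) -> TreatedBlock:
    """Apply one Parameter-1 option to a (ceiling-cleaned) latency vector.

    Statistical options operate on sorted order statistics of the vector they
    are given; trial order never affects the scored multiset.
    """
    x = np.asarray(latencies, dtype=float)
    bk = Bookkeeping(n_input=x.size)
    code = option.code

    if code == "none":
        out = x
    elif code == "fixed_trim":
        keep = x >= option.fixed_trim_lower
        bk.n_treatment_removed = int((~keep).sum())
        out = x[keep]
    elif code == "fixed_winsor":
        bk.n_winsorized = int(
            ((x < option.winsor_lower) | (x > option.winsor_upper)).sum()
        )
        out = np.clip(x, option.winsor_lower, option.winsor_upper)
    else:
        out, bk = _statistical_treatment(x, option, bk)

    bk.n_scored = out.size
    if out.size == 0 and x.size > 0:
        bk.degenerate = True
        bk.reason = bk.reason or "all_latencies_removed"
    return TreatedBlock(out, bk)


def _statistical_treatment(
    x: np.ndarray, option: LatencyTreatmentOption, bk: Bookkeeping
) -> tuple[np.ndarray, Bookkeeping]:
    n = x.size
    k = _tail_k(n, option.proportion)
    if n == 0:
        return x, bk
    s = np.sort(x, kind="stable")
    code = option.code
    if code == "stat_trim":
        if 2 * k >= n:
            bk.n_treatment_removed = n
            bk.degenerate = True
            bk.reason = "trim_removed_all"
            return x[:0], bk
        bk.n_treatment_removed = 2 * k
        return s[k : n - k], bk
    if code == "stat_winsor":
        if k == 0:
            return s, bk
        if 2 * k >= n:
            bk.degenerate = True
            bk.reason = "winsor_no_retained_value"
            return x[:0], bk
        out = s.copy()
        out[:k] = s[k]
        out[n - k :] = s[n - k - 1]
        bk.n_winsorized = 2 * k
        return out, bk
    # stat_inverse_trim: remove the k retained values adjacent to the median
    # on each side.  Even n: the two central order statistics and outward;
    # odd n: the median itself is retained and its k neighbours on each side
    # are removed, so exactly 2k values go for every n.
    if k == 0:
        return s, bk
    if n % 2 == 0:
        lo_stop = n // 2  # exclusive upper end of lower removal window
        hi_start = n // 2
    else:
        lo_stop = (n - 1) // 2
        hi_start = lo_stop + 1
    lo_start = max(lo_stop - k, 0)
    hi_stop = min(hi_start + k, n)
    keep = np.ones(n, dtype=bool)
    keep[lo_start:lo_stop] = False
    keep[hi_start:hi_stop] = False
    bk.n_treatment_removed = int((~keep).sum())
    out = s[keep]
    if out.size == 0:
        bk.degenerate = True
        bk.reason = "inverse_trim_removed_all"
    return out, bk


def apply_error_treatment(
    latencies: np.ndarray,
    is_error: np.ndarray,
    e_opt: ErrorTreatmentOption,
    l_opt: LatencyTreatmentOption,
) -> TreatedBlock:
    """Compose Parameter 2 with Parameter 1 for one critical block.

    The 10 s ceiling is applied here, first, to correct and error trials
    alike. Recode baselines (mean, SD) are computed on the *treated* correct
    latencies of the same block; sample (n-1) SD throughout.
    """
    latencies = np.asarray(latencies, dtype=float)
    is_error = np.asarray(is_error, dtype=bool)
    if latencies.shape != is_error.shape:
        raise ValueError("latency and error vectors must have equal length")

    n_input = latencies.size
    keep = latencies <= CEILING_MS
    n_ceiling = int((~keep).sum())
    lat, err = latencies[keep], is_error[keep]
    code = e_opt.code

    if code == "ignore":
        block = apply_latency_treatment(lat, l_opt)
    elif code == "exclude":
        block = apply_latency_treatment(lat[~err], l_opt)
        block.bookkeeping.n_input += int(err.sum())
        block.bookkeeping.n_errors_excluded = int(err.sum())
    elif code == "separate":
        correct = apply_latency_treatment(lat[~err], l_opt)
        errors = apply_latency_treatment(lat[err], l_opt)
        block = TreatedBlock(
            np.concatenate([correct.latencies, errors.latencies]),
            correct.bookkeeping.merge(errors.bookkeeping),
        )
    elif code in ("recode_2sd", "recode_600"):
        correct = apply_latency_treatment(lat[~err], l_opt)
        n_err = int(err.sum())
        bk = correct.bookkeeping
        bk.n_input += n_err
        treated = correct.latencies
        if n_err == 0:
            block = TreatedBlock(treated, bk)
        elif treated.size < 2:
            bk.degenerate = True
            bk.reason = "recode_baseline_needs_2_correct"
            bk.n_errors_excluded = n_err  # dropped: no baseline to recode against
            block = TreatedBlock(treated, bk)
        else:
            mean = float(np.mean(treated))
            if code == "recode_600":
                penalty = e_opt.penalty_ms
            else:
                penalty = e_opt.penalty_sd_multiplier * float(np.std(treated, ddof=1))
            # scored values never exceed the global ceiling
            recoded = np.full(n_err, min(mean + penalty, CEILING_MS))
            bk.n_errors_recoded = n_err
            block = TreatedBlock(np.concatenate([treated, recoded]), bk)
        block.bookkeeping.n_scored = block.latencies.size
    else:  # pragma: no cover - guarded by ErrorTreatmentOption
        raise ValueError(code)

    block.bookkeeping.n_input = n_input
    block.bookkeeping.n_over_ceiling = n_ceiling
    block.bookkeeping.n_scored = block.latencies.size
    # the scored set is a multiset; returning it sorted makes logically
    # equivalent treatment paths (Ignore vs Separate under fixed-value
    # options) bit-identical downstream
    block.latencies = np.sort(block.latencies, kind="stable")
    return block


def latency_option(code: str, **kwargs) -> LatencyTreatmentOption:
    return LatencyTreatmentOption(code=code, **kwargs)


def error_option(code: str, **kwargs) -> ErrorTreatmentOption:
    return ErrorTreatmentOption(code=code, **kwargs)
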