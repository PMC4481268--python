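"""Synthetic IAT sessions with the statistical structure the scoring
comparison assumes.

Each subject carries a latent preference theta ~ N(0, 1). Latencies are
ex-Gaussian (the standard positively skewed reaction-time family) with a
per-subject general-speed offset; the incompatible/compatible blocks are
shifted by +/- delta_ms * theta / 2. Errors occur with a base probability
plus an increment in the incompatible pairing; under a built-in-penalty
procedure the recorded error latency includes a positive correction time.
Contamination injects fast guesses (< 300 ms) and attentional lapses (up
to the 10 s ceiling and slightly beyond, so ceiling handling is
exercised). Criterion measures are loading * theta + noise, oriented so
higher = stronger target-consistent preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trialdata import PAIRINGS, CriterionPanel, TrialTable


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration. Defaults emulate the classic 7-block IAT
    critical structure: 20 practice + 40 test trials per pairing (60 per
    critical block)."""

    n_subjects: int = 100
    practice_trials: int = 20
    test_trials: int = 40
    # ex-Gaussian latency model, milliseconds
    mu_ms: float = 600.0
    sigma_ms: float = 100.0
    tau_ms: float = 150.0
    subject_speed_sd_ms: float = 80.0
    # latent effect: incompatible-minus-compatible shift = delta_ms * theta
    delta_ms: float = 150.0
    # error model
    error_rate_base: float = 0.05
    error_rate_incompatible_increment: float = 0.03
    # built-in penalty: correction time added to error latencies
    built_in: bool = False
    correction_mu_ms: float = 300.0
    correction_tau_ms: float = 150.0
    # contamination
    fast_guess_rate: float = 0.02
    lapse_rate: float = 0.01
    # criterion measures: per-role loadings on theta and noise SDs
    criterion_loadings: dict = field(
        default_factory=lambda: {
            "direct": [0.5, 0.4],
            "indirect": [0.45, 0.35],
            "behavioral": [0.3],
        }
    )
    criterion_noise_sd: float = 1.0
    # sessions
    n_sessions: int = 1
    retest_stability: float = 0.8
    seed: int = 0
    dataset_label: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("error_rate_base", "error_rate_incompatible_increment",
                     "fast_guess_rate", "lapse_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        for name in ("sigma_ms", "tau_ms", "subject_speed_sd_ms",
                     "criterion_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 <= self.retest_stability <= 1:
            raise ValueError("retest_stability must be in [-1, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")


def _ex_gaussian(rng: np.random.Generator, n: int, mu: float, sigma: float,
                 tau: float) -> np.ndarray:
    return rng.normal(mu, sigma, n) + rng.exponential(tau, n)


def _session_trials(
    rng: np.random.Generator, config: SynthConfig, subject_ids, theta: np.ndarray,
    session: int,
) -> pd.DataFrame:
    rows = []
    inc_rate = min(
        1.0, config.error_rate_base + config.error_rate_incompatible_increment
    )
    for subj, th in zip(subject_ids, theta):
        speed = rng.normal(0.0, config.subject_speed_sd_ms)
        for pairing in PAIRINGS:
            shift = (config.delta_ms * th / 2) * (
                1 if pairing == "incompatible" else -1
            )
            err_rate = inc_rate if pairing == "incompatible" else config.error_rate_base
            for phase, n_trials in (
                ("practice", config.practice_trials),
                ("test", config.test_trials),
            ):
                lat = _ex_gaussian(
                    rng, n_trials, config.mu_ms + speed + shift,
                    config.sigma_ms, config.tau_ms,
                )
                err = rng.random(n_trials) < err_rate
                if config.built_in and err.any():
                    lat[err] += config.correction_mu_ms + rng.exponential(
                        config.correction_tau_ms, int(err.sum())
                    )
                # contamination: fast guesses then lapses, non-overlapping
                u = rng.random(n_trials)
                fast = u < config.fast_guess_rate
                lapse = (u >= config.fast_guess_rate) & (
                    u < config.fast_guess_rate + config.lapse_rate
                )
                lat[fast] = rng.uniform(120.0, 295.0, int(fast.sum()))
                lat[lapse] = rng.uniform(4000.0, 11_000.0, int(lapse.sum()))
                lat = np.maximum(lat, 80.0)  # latencies must stay positive
                for t in range(n_trials):
                    rows.append(
                        (subj, session, pairing, phase, float(lat[t]), bool(err[t]))
                    )
    return pd.DataFrame(
        rows, columns=["subject", "session", "pairing", "phase", "latency_ms", "error"]
    )


def generate(config: SynthConfig) -> tuple[TrialTable, CriterionPanel]:
    """Generate one synthetic dataset (trials + criterion panel), fully
    determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    subject_ids = [f"s{i + 1:04d}" for i in range(config.n_subjects)]
    theta = rng.standard_normal(config.n_subjects)

    frames = [_session_trials(rng, config, subject_ids, theta, session=1)]
    if config.n_sessions == 2:
        rho = config.retest_stability
        theta2 = rho * theta + np.sqrt(1 - rho**2) * rng.standard_normal(
            config.n_subjects
        )
        frames.append(_session_trials(rng, config, subject_ids, theta2, session=2))
    table = TrialTable(
        pd.concat(frames, ignore_index=True),
        built_in_penalty=config.built_in,
        dataset_label=config.dataset_label,
    )

    measures, roles = {}, {}
    for role, loadings in config.criterion_loadings.items():
        for i, loading in enumerate(loadings, start=1):
            name = f"{role}_{i}"
            measures[name] = loading * theta + rng.normal(
                0.0, config.criterion_noise_sd, config.n_subjects
            )
            roles[name] = role
    panel = CriterionPanel(
        pd.DataFrame(measures, index=pd.Index(subject_ids, name="subject")), roles
    )
    return table, panel


def latent_preference(config: SynthConfig) -> pd.Series:
    """The theta vector ``generate`` used, recomputed from the seed (the
    generator draws it first, so this is exact)."""
    rng = np.random.default_rng(config.seed)
    subject_ids = [f"s{i + 1:04d}" for i in range(config.n_subjects)]
    return pd.Series(
        rng.standard_normal(config.n_subjects),
        index=pd.Index(subject_ids, name="subject"),
        name="theta",
    )


def default_study_configs(seed: int = 0, n_subjects: int = 100) -> list[SynthConfig]:
    """Six-dataset study layout: three built-in-penalty datasets (with a
    retest session, mirroring large online collections) and three
    no-built-in datasets (single session, lab-style)."""
    configs = []
    for i in range(3):
        configs.append(
            SynthConfig(
                n_subjects=n_subjects,
                built_in=True,
                n_sessions=2,
                seed=seed * 1000 + i,
                dataset_label=f"builtin_{i + 1}",
            )
        )
    for i in range(3):
        configs.append(
            SynthConfig(
                n_subjects=n_subjects,
                built_in=False,
                n_sessions=1,
                seed=seed * 1000 + 100 + i,
                dataset_label=f"nobuiltin_{i + 1}",
            )
        )
    return configs


def generate_multidataset(
    configs: list[SynthConfig],
) -> list[tuple[TrialTable, CriterionPanel]]:
    """Generate a list of tagged datasets (e.g., the 3 built-in + 3
    no-built-in study layout) for the downstream rank/ANOVA layer."""
    if not configs:
        raise ValueError("need at least one config")
    return [generate(c) for c in configs]
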