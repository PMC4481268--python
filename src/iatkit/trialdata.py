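"""Domain types and I/O for IAT trial data and criterion panels.

The canonical in-memory representation is long format: one row per trial,
ordered as administered (within-block order is load-bearing — odd/even
reliability splits depend on it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

PAIRINGS = ("compatible", "incompatible")
PHASES = ("practice", "test")

#: canonical column names; external spellings are mapped onto these
REQUIRED_COLUMNS = ("subject", "pairing", "phase", "latency_ms", "error")
OPTIONAL_COLUMNS = ("session", "block_index")


class TrialDataError(ValueError):
    """Raised for malformed or invariant-violating trial data."""


@dataclass(frozen=True)
class TrialTable:
    """Ordered per-trial IAT records for one dataset.

    Parameters
    ----------
    trials : pandas.DataFrame
        Long-format trials with canonical columns ``subject``, ``session``,
        ``pairing`` (compatible/incompatible), ``phase`` (practice/test),
        ``latency_ms`` (> 0, milliseconds) and ``error`` (bool). Row order is
        the within-block presentation order.
    built_in_penalty : bool
        True when the IAT procedure forced error correction, so recorded
        latencies already contain the correction time.
    dataset_label : str
        Free-text identifier used in reports.
    """

    trials: pd.DataFrame
    built_in_penalty: bool = False
    dataset_label: str = "unnamed"

    def __post_init__(self) -> None:
        df = self.trials
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TrialDataError(f"missing required columns: {missing}")
        if "session" not in df.columns:
            df = df.assign(session=1)
        lat = pd.to_numeric(df["latency_ms"], errors="coerce")
        bad = df.index[~(lat > 0) | lat.isna()]
        if len(bad):
            raise TrialDataError(
                f"non-positive or unparseable latency at row(s) {list(bad[:10])}"
            )
        for col, allowed in (("pairing", PAIRINGS), ("phase", PHASES)):
            extra = set(df[col].unique()) - set(allowed)
            if extra:
                raise TrialDataError(f"invalid {col} values: {sorted(extra)}")
        df = df.assign(latency_ms=lat.astype(float), error=df["error"].astype(bool))
        object.__setattr__(self, "trials", df.reset_index(drop=True))

    @property
    def subjects(self) -> list:
        return sorted(self.trials["subject"].unique().tolist())

    @property
    def sessions(self) -> list[int]:
        return sorted(int(s) for s in self.trials["session"].unique())

    def for_session(self, session: int) -> "TrialTable":
        sub = self.trials[self.trials["session"] == session]
        return TrialTable(sub.copy(), self.built_in_penalty, self.dataset_label)


@dataclass(frozen=True)
class CriterionPanel:
    """Per-subject criterion measures, oriented so higher = stronger
    target-consistent preference.

    ``measures`` is one row per subject (index = subject id); ``roles`` maps
    each measure column to ``direct`` | ``indirect`` | ``behavioral``.
    """

    measures: pd.DataFrame
    roles: Mapping[str, str] = field(default_factory=dict)

    VALID_ROLES = ("direct", "indirect", "behavioral")

    def __post_init__(self) -> None:
        unknown = {m: r for m, r in self.roles.items() if r not in self.VALID_ROLES}
        if unknown:
            raise TrialDataError(f"invalid measure roles: {unknown}")
        stray = set(self.roles) - set(self.measures.columns)
        if stray:
            raise TrialDataError(f"roles for unknown measures: {sorted(stray)}")

    def measures_for_role(self, role: str) -> list[str]:
        return [m for m in self.measures.columns if self.roles.get(m) == role]


def _resolve_dialect(columns, dialect: Mapping[str, str] | None) -> dict:
    """Map canonical names to the file's column names."""
    dialect = dict(dialect or {})
    mapping = {}
    for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        source = dialect.get(canon, canon)
        if source in columns:
            mapping[canon] = source
    missing = [c for c in REQUIRED_COLUMNS if c not in mapping]
    if missing:
        raise TrialDataError(
            f"cannot resolve required column(s) {missing} "
            f"(file has {list(columns)}; dialect {dialect})"
        )
    return mapping


_TRUTHY = {"1", "true", "t", "yes", "y", "error"}
_FALSY = {"0", "false", "f", "no", "n", "correct", ""}


def _parse_error_flag(values: pd.Series) -> pd.Series:
    if values.dtype == bool:
        return values
    as_str = values.astype(str).str.strip().str.lower()
    out = pd.Series(np.nan, index=values.index, dtype=object)
    out[as_str.isin(_TRUTHY)] = True
    out[as_str.isin(_FALSY)] = False
    bad = out.index[out.isna()]
    if len(bad):
        raise TrialDataError(f"unparseable error flag at row(s) {list(bad[:10])}")
    return out.astype(bool)


def read_trials(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    built_in_penalty: bool = False,
    dataset_label: str | None = None,
) -> TrialTable:
    """Read a long-format trial CSV/TSV into a validated :class:`TrialTable`.

    ``dialect`` maps canonical column names (``subject``, ``pairing``,
    ``phase``, ``latency_ms``, ``error``, optionally ``session``,
    ``block_index``) to the file's own headers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep)
    mapping = _resolve_dialect(raw.columns, dialect)
    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    df["error"] = _parse_error_flag(df["error"])
    if "session" not in df.columns:
        df["session"] = 1
    lat = pd.to_numeric(df["latency_ms"], errors="coerce")
    bad = df.index[lat.isna() | (lat <= 0)]
    if len(bad):
        raise TrialDataError(
            f"invalid latency value(s) at row(s) {[int(i) + 2 for i in bad[:10]]} "
            f"of {path.name} (1-based, incl. header)"
        )
    return TrialTable(
        df,
        built_in_penalty=built_in_penalty,
        dataset_label=dataset_label or path.stem,
    )


def write_trials(table: TrialTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in table.trials.columns]
    out = table.trials[cols].copy()
    out["error"] = out["error"].astype(int)
    out.to_csv(path, sep=sep, index=False)


def read_criteria(path: str | Path, roles_path: str | Path | None = None) -> CriterionPanel:
    """Read a criterion panel CSV (one row per subject, first column = subject id)
    plus its JSON role sidecar mapping measure -> direct|indirect|behavioral."""
    path = Path(path)
    df = pd.read_csv(path).set_index("subject")
    if roles_path is None:
        roles_path = path.with_suffix(".roles.json")
    roles = json.loads(Path(roles_path).read_text()) if Path(roles_path).exists() else {}
    return CriterionPanel(df, roles)


def write_criteria(panel: CriterionPanel, path: str | Path) -> None:
    path = Path(path)
    panel.measures.rename_axis("subject").to_csv(path)
    path.with_suffix(".roles.json").write_text(json.dumps(dict(panel.roles), indent=2))


def validate_structure(table: TrialTable) -> pd.DataFrame:
    """Per-subject per-pairing per-phase trial counts, with flags.

    A subject is flagged when a pairing is missing entirely, or when a phase
    is missing within a pairing (the latter only matters for algorithms that
    score practice and test trials separately). Report-only: no exception is
    raised for flagged subjects.
    """
    if table.trials.empty:
        raise TrialDataError("empty trial table")
    counts = (
        table.trials.groupby(["subject", "pairing", "phase"], observed=False)
        .size()
        .rename("n_trials")
        .reset_index()
    )
    full = pd.MultiIndex.from_product(
        [table.subjects, PAIRINGS, PHASES], names=["subject", "pairing", "phase"]
    )
    counts = (
        counts.set_index(["subject", "pairing", "phase"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    pair_tot = counts.groupby(["subject", "pairing"])["n_trials"].transform("sum")
    counts["missing_pairing"] = pair_tot == 0
    counts["missing_phase"] = (counts["n_trials"] == 0) & ~counts["missing_pairing"]
    counts["flagged"] = counts["missing_pairing"] | counts["missing_phase"]
    return counts
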