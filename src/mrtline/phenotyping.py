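"""Classification of assay lines into mortal-germline (Mrt) phenotype classes.

A line is assayed as a set of replicates, each propagated at 25°C until it
either goes sterile at some generation or survives (right-censored) to the
assay horizon (21 generations for the full design, 14 for the truncated one).
The classifier applies threshold rules on the mean and maximum time to
sterility:

* ``strong``    — every informative replicate went sterile, mean time to
  sterility < 10 generations and maximum < 15.
* ``moderate``  — every informative replicate sterile by the 21-generation
  horizon and mean time to sterility < 16.
* ``weak``      — at least 2/3 of informative replicates sterile by
  generation 21 (the "2 out of 3" rule, extended proportionally to
  replicate counts other than 3).
* ``wild_type`` — none of the above (in the 3-replicate design this is
  exactly "at least 2 of 3 replicates fertile at generation 21").
* ``ts_sterile`` — every replicate sterile after the first generation at
  25°C; classic temperature-sensitive sterility, distinct from the
  progressive Mrt kinetics.
* ``excluded_low_fitness`` — the majority of replicates failed for reasons
  unrelated to Mrt (sickly, slow-growing lines); such lines are excluded
  from Mrt scoring.

Replicates annotated ``non_mrt_failure`` are excluded from the timing
computations; censored replicates never contribute to the mean.

Assays truncated before generation 21 cannot distinguish moderate or weak
Mrt from wild type (both categories are defined by generation-21 fertility),
so for horizons < 21 the classifier only returns ``ts_sterile``, ``strong``,
``excluded_low_fitness`` or ``wild_type`` and logs a caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MrtClass",
    "FailureMode",
    "ReplicateOutcome",
    "LineAssay",
    "MeanTimeToSterility",
    "mean_time_to_sterility",
    "classify_line",
    "classify_table",
    "compare_time_to_failure",
    "FULL_ASSAY_HORIZON",
    "TABLE_COLUMNS",
]

#: Horizon of the full assay design; the moderate and weak categories are
#: defined in terms of fertility at this generation.
FULL_ASSAY_HORIZON = 21

# Classification thresholds (generations); strict inequalities throughout.
STRONG_MEAN_LT = 10
STRONG_MAX_LT = 15
MODERATE_MEAN_LT = 16
WEAK_STERILE_FRACTION = 2.0 / 3.0

#: Canonical column order of assay tables.
TABLE_COLUMNS = ["line_id", "replicate_id", "sterile_generation", "censored", "failure_mode"]


class MrtClass(str, Enum):
    """Phenotype category of an assay line."""

    TS_STERILE = "ts_sterile"
    EXCLUDED_LOW_FITNESS = "excluded_low_fitness"
    STRONG = "strong"
    MODERATE = "moderate"
    WEAK = "weak"
    WILD_TYPE = "wild_type"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Severity ordering of the Mrt continuum (larger = stronger phenotype).
#: ts_sterile sits above strong: it is immediate, fully penetrant sterility.
MRT_SEVERITY = {
    MrtClass.WILD_TYPE: 0,
    MrtClass.WEAK: 1,
    MrtClass.MODERATE: 2,
    MrtClass.STRONG: 3,
    MrtClass.TS_STERILE: 4,
}


class FailureMode(str, Enum):
    """Why a replicate failed to finish the assay (``none`` if it finished)."""

    MRT_STERILE = "mrt_sterile"
    NON_MRT_FAILURE = "non_mrt_failure"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ReplicateOutcome:
    """Fate of one replicate of one line in the Mrt assay."""

    line_id: str
    replicate_id: str
    sterile_generation: int | None
    censored: bool
    failure_mode: str = FailureMode.NONE.value

    def __post_init__(self) -> None:
        if self.censored:
            if self.sterile_generation is not None:
                raise ValueError(
                    f"censored replicate {self.line_id}/{self.replicate_id} "
                    "must not carry a sterile_generation"
                )
        else:
            if self.sterile_generation is None:
                raise ValueError(
                    f"uncensored replicate {self.line_id}/{self.replicate_id} "
                    "must carry a sterile_generation"
                )
            if self.sterile_generation < 1:
                raise ValueError("sterile_generation must be >= 1")
        FailureMode(self.failure_mode)  # validates


@dataclass
class LineAssay:
    """All replicate outcomes of one line, plus the assay horizon."""

    line_id: str
    outcomes: list[ReplicateOutcome] = field(default_factory=list)
    horizon: int = FULL_ASSAY_HORIZON

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError(f"line {self.line_id}: at least one replicate outcome required")
        for o in self.outcomes:
            if o.line_id != self.line_id:
                raise ValueError(
                    f"outcome line_id {o.line_id!r} does not match line {self.line_id!r}"
                )
            if not o.censored and o.sterile_generation > self.horizon:
                raise ValueError(
                    f"line {self.line_id}: sterile_generation {o.sterile_generation} "
                    f"exceeds assay horizon {self.horizon}"
                )


@dataclass(frozen=True)
class MeanTimeToSterility:
    """Mean generation-at-sterility over the informative sterile replicates.

    ``mean`` is ``None`` when no informative replicate went sterile.  The
    counts refer to informative replicates only (those not annotated as
    non-Mrt failures).
    """

    mean: float | None
    n_sterile: int
    n_censored: int


def _line_arrays(line: LineAssay) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    gens = np.array(
        [0 if o.censored else o.sterile_generation for o in line.outcomes], dtype=float
    )
    censored = np.array([o.censored for o in line.outcomes], dtype=bool)
    non_mrt = np.array(
        [o.failure_mode == FailureMode.NON_MRT_FAILURE.value for o in line.outcomes],
        dtype=bool,
    )
    return gens, censored, non_mrt


def _mean_time_core(
    gens: np.ndarray, censored: np.ndarray, non_mrt: np.ndarray
) -> MeanTimeToSterility:
    informative = ~non_mrt
    sterile = informative & ~censored
    n_sterile = int(sterile.sum())
    n_censored = int((informative & censored).sum())
    mean = float(gens[sterile].mean()) if n_sterile else None
    return MeanTimeToSterility(mean=mean, n_sterile=n_sterile, n_censored=n_censored)


def mean_time_to_sterility(line: LineAssay) -> MeanTimeToSterility:
    """Mean time to sterility of a line, censored replicates excluded.

    Non-Mrt failures (low-fitness deaths) are excluded from both the mean
    and the counts; censored replicates contribute only to ``n_censored``.
    """
    gens, censored, non_mrt = _line_arrays(line)
    return _mean_time_core(gens, censored, non_mrt)


def _classify_core(
    gens: np.ndarray,
    censored: np.ndarray,
    non_mrt: np.ndarray,
    horizon: int,
) -> tuple[MrtClass, MeanTimeToSterility]:
    """Classification rules on raw per-replicate arrays.

    Precedence: ts_sterile, excluded_low_fitness, strong, moderate, weak,
    wild_type; the first matching rule wins.
    """
    n = gens.shape[0]
    diag = _mean_time_core(gens, censored, non_mrt)

    # All replicates (regardless of annotation) sterile in the first
    # generation at restrictive temperature: heat-sensitive sterile, not Mrt.
    if not censored.any() and (gens == 1).all():
        return MrtClass.TS_STERILE, diag

    # Majority of replicates failed for reasons unrelated to Mrt.
    if int(non_mrt.sum()) * 2 > n:
        return MrtClass.EXCLUDED_LOW_FITNESS, diag

    informative = ~non_mrt
    n_informative = int(informative.sum())
    if n_informative == 0:
        # Half the replicates are non-Mrt failures and none are informative:
        # no Mrt evidence either way.
        return MrtClass.WILD_TYPE, diag

    sterile = informative & ~censored
    all_sterile = diag.n_censored == 0 and diag.n_sterile == n_informative
    max_gen = float(gens[sterile].max()) if diag.n_sterile else np.inf

    if (
        all_sterile
        and diag.mean is not None
        and diag.mean < STRONG_MEAN_LT
        and max_gen < STRONG_MAX_LT
    ):
        return MrtClass.STRONG, diag

    if horizon < FULL_ASSAY_HORIZON:
        # moderate and weak are defined by fertility at generation 21, which
        # a truncated assay cannot observe.
        logger.debug(
            "horizon %d < %d: moderate/weak Mrt cannot be scored; "
            "falling back to wild_type",
            horizon,
            FULL_ASSAY_HORIZON,
        )
        return MrtClass.WILD_TYPE, diag

    if all_sterile and diag.mean is not None and diag.mean < MODERATE_MEAN_LT:
        return MrtClass.MODERATE, diag

    if 3 * diag.n_sterile >= 2 * n_informative:  # >= 2/3 sterile, exact in integers
        return MrtClass.WEAK, diag

    return MrtClass.WILD_TYPE, diag


def classify_line(line: LineAssay) -> MrtClass:
    """Assign an Mrt class to a line from its replicate outcomes."""
    gens, censored, non_mrt = _line_arrays(line)
    cls, _ = _classify_core(gens, censored, non_mrt, line.horizon)
    return cls


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"assay table is missing columns: {missing}")
    dup = table.duplicated(subset=["line_id", "replicate_id"])
    if dup.any():
        bad = table.loc[dup, ["line_id", "replicate_id"]].iloc[0]
        raise ValueError(
            f"duplicate line x replicate key: {bad['line_id']}/{bad['replicate_id']}"
        )
    return table


def classify_table(
    table: pd.DataFrame, horizon: int = FULL_ASSAY_HORIZON
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every line of an assay table.

    Parameters
    ----------
    table
        Tidy assay table with columns ``line_id, replicate_id,
        sterile_generation, censored, failure_mode`` (one row per
        line x replicate; ``sterile_generation`` empty/NaN when censored).
    horizon
        Generation at which surviving replicates were censored.

    Returns
    -------
    per_line, counts
        ``per_line`` has one row per line (``line_id, mrt_class,
        mean_time_to_sterility, n_sterile, n_censored``); ``counts`` maps
        every class name to the number of lines assigned to it (zeros
        included), summing to the number of lines.
    """
    _validate_table(table)
    if len(table) == 0:
        per_line = pd.DataFrame(
            columns=["line_id", "mrt_class", "mean_time_to_sterility", "n_sterile", "n_censored"]
        )
        return per_line, {c.value: 0 for c in MrtClass}

    if horizon < FULL_ASSAY_HORIZON:
        logger.warning(
            "assay horizon %d < %d generations: moderate and weak Mrt cannot be "
            "distinguished from wild type in this design",
            horizon,
            FULL_ASSAY_HORIZON,
        )

    censored = table["censored"].astype(bool).to_numpy()
    gens_raw = pd.to_numeric(table["sterile_generation"], errors="coerce").to_numpy(dtype=float)
    if np.isnan(gens_raw[~censored]).any():
        raise ValueError("uncensored replicate without a sterile_generation")
    gens = np.where(censored, 0.0, gens_raw)
    if (gens[~censored] > horizon).any():
        raise ValueError(
            f"sterile_generation exceeds the assay horizon {horizon}; "
            "check the horizon argument"
        )
    if (gens[~censored] < 1).any():
        raise ValueError("sterile_generation must be >= 1")
    non_mrt = (table["failure_mode"] == FailureMode.NON_MRT_FAILURE.value).to_numpy()

    records = []
    grouped = table.groupby("line_id", sort=True).indices
    for line_id, idx in grouped.items():
        cls, diag = _classify_core(gens[idx], censored[idx], non_mrt[idx], horizon)
        records.append(
            {
                "line_id": line_id,
                "mrt_class": cls.value,
                "mean_time_to_sterility": diag.mean,
                "n_sterile": diag.n_sterile,
                "n_censored": diag.n_censored,
            }
        )
    per_line = pd.DataFrame.from_records(records)
    counts = {c.value: 0 for c in MrtClass}
    counts.update(per_line["mrt_class"].value_counts().to_dict())
    return per_line, counts


# ---------------------------------------------------------------------------
# MA vs pseudoline time-to-failure comparison
# ---------------------------------------------------------------------------


def _failure_times(table: pd.DataFrame, horizon: int) -> np.ndarray:
    """Replicate-level time to failure; censored replicates score the horizon."""
    _validate_table(table)
    censored = table["censored"].astype(bool).to_numpy()
    gens = pd.to_numeric(table["sterile_generation"], errors="coerce").to_numpy(dtype=float)
    return np.where(censored, float(horizon), gens)


def _ks_distances(
    pooled_sorted: np.ndarray, labels_sorted: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """KS distance for each row of a (B, n) boolean label matrix.

    ``labels_sorted`` marks membership in sample 1, rows aligned to the
    sorted pooled values; ties are handled by evaluating the ECDF difference
    only at the last index of each tie group.
    """
    cum1 = np.cumsum(labels_sorted, axis=-1) / n1
    cum2 = np.cumsum(~labels_sorted, axis=-1) / n2
    diff = np.abs(cum1 - cum2)
    # positions where the next pooled value differs (tie-group boundaries)
    boundary = np.empty(pooled_sorted.shape[0], dtype=bool)
    boundary[:-1] = pooled_sorted[1:] != pooled_sorted[:-1]
    boundary[-1] = True
    return diff[..., boundary].max(axis=-1)


@dataclass(frozen=True)
class TwoSampleResult:
    """Kolmogorov–Smirnov distance and its permutation p-value."""

    statistic: float
    p_value: float
    n_permutations: int


def compare_time_to_failure(
    ma_table: pd.DataFrame,
    ps_table: pd.DataFrame,
    horizon: int = FULL_ASSAY_HORIZON,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> TwoSampleResult:
    """Compare replicate-level time-to-failure distributions of two tables.

    The statistic is the two-sample Kolmogorov–Smirnov distance between the
    replicate-level times to failure (censored replicates assigned the
    horizon).  Significance comes from a label-permutation null with +1
    smoothing, so the p-value is in (0, 1].
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    a = _failure_times(ma_table, horizon)
    b = _failure_times(ps_table, horizon)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both tables must contain at least one replicate")

    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    order = np.argsort(pooled, kind="mergesort")
    pooled_sorted = pooled[order]
    labels = np.zeros(n1 + n2, dtype=bool)
    labels[:n1] = True
    observed = float(_ks_distances(pooled_sorted, labels[order][None, :], n1, n2)[0])

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(labels, (n_permutations, 1)), axis=1)
    perm_stats = _ks_distances(pooled_sorted, perm[:, order], n1, n2)
    n_ge = int((perm_stats >= observed - 1e-12).sum())
    p = (1 + n_ge) / (n_permutations + 1)
    return TwoSampleResult(statistic=observed, p_value=p, n_permutations=n_permutations)
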