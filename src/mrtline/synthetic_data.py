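"""Synthetic Mrt assay tables with the statistical structure of the real assay.

The generator emulates the two experimental designs:

* MA design — 34 N2 lines x 10 replicates censored at 21 generations and
  33 PB306 lines x 10 replicates censored at 14 generations, each with 18
  ancestral pseudolines x 10 replicates as controls;
* wild-isolate design — 95 strains x 3 replicates censored at 21
  generations.

Each line belongs to a latent phenotype class (strong/moderate/weak Mrt,
wild type, ts-sterile, or low-fitness contaminant) drawn from a mixture.
Replicates of a line then draw a generation-at-sterility from the class's
sterility model, or are right-censored at the assay horizon.  The default
per-class models are horizon-truncated shifted negative binomials
parameterized so that generated lines satisfy the corresponding
classification rules with high probability; the class definitions fix only
the thresholds, so the generative law itself is a package convention and
every parameter is overridable.

Low-fitness lines emulate sickly MA lines whose replicates die for reasons
unrelated to Mrt; their failures carry the ``non_mrt_failure`` annotation
(in the real assay this call is made by visual inspection, here it is
generated).

Seeding: a single integer seed expands into per-line substreams
(`numpy` ``SeedSequence.spawn``), so generating more lines never perturbs
the outcomes of earlier lines, and the same configuration and seed always
reproduce a byte-identical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phenotyping import FULL_ASSAY_HORIZON, FailureMode, TABLE_COLUMNS

__all__ = [
    "AssayDesign",
    "ClassSterilityModel",
    "SyntheticConfig",
    "ConfigurationError",
    "DEFAULT_STERILITY_MODELS",
    "N2_MA_DESIGN",
    "PB306_MA_DESIGN",
    "PSEUDOLINE_DESIGN",
    "WILD_ISOLATE_DESIGN",
    "draw_line_classes",
    "generate_assay_table",
    "generate_ma_experiment",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration (e.g. a mixture not summing to 1)."""


@dataclass(frozen=True)
class AssayDesign:
    """Shape of an Mrt assay: lines x replicates, censored at a horizon."""

    n_lines: int
    reps_per_line: int
    assay_generations: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.reps_per_line < 1 or self.assay_generations < 1:
            raise ConfigurationError("all design counts must be >= 1")


#: The study designs.
N2_MA_DESIGN = AssayDesign(34, 10, 21, "N2 MA lines")
PB306_MA_DESIGN = AssayDesign(33, 10, 14, "PB306 MA lines")
PSEUDOLINE_DESIGN = AssayDesign(18, 10, 21, "G0 pseudolines")
WILD_ISOLATE_DESIGN = AssayDesign(95, 3, 21, "wild isolates")


@dataclass(frozen=True)
class ClassSterilityModel:
    """Distribution of generation-at-sterility for one phenotype class.

    ``sterility_prob`` is the per-replicate probability of going sterile
    before the horizon; surviving replicates are right-censored.  Families:

    * ``negative_binomial`` — generation = 1 + NB(mean ``mean_generation``-1,
      shape ``shape``), truncated at the horizon.  Larger ``shape`` means
      tighter dispersion (variance = m + m^2/shape for the NB part).
    * ``uniform`` — discrete uniform on [``low``, ``high``], truncated at
      the horizon.
    * ``degenerate`` — all mass at generation ``low`` (e.g. ts-sterile at 1).
    """

    sterility_prob: float
    family: str = "negative_binomial"
    mean_generation: float = 6.0
    shape: float = 50.0
    low: int = 1
    high: int = 1
    failure_mode: str = FailureMode.MRT_STERILE.value

    def __post_init__(self) -> None:
        if not 0 <= self.sterility_prob <= 1:
            raise ConfigurationError("sterility_prob must be in [0, 1]")
        if self.family not in ("negative_binomial", "uniform", "degenerate"):
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if self.family == "negative_binomial" and self.mean_generation < 1:
            raise ConfigurationError("mean_generation must be >= 1")
        if self.low < 1 or self.high < self.low:
            raise ConfigurationError("need 1 <= low <= high")

    def sample(self, rng: np.random.Generator, size: int, horizon: int) -> np.ndarray:
        """Draw ``size`` sterile generations, each an integer in [1, horizon]."""
        if self.family == "degenerate":
            gens = np.full(size, self.low, dtype=np.int64)
        elif self.family == "uniform":
            gens = rng.integers(self.low, self.high + 1, size=size)
        else:
            m = self.mean_generation - 1.0
            if m <= 0:
                gens = np.ones(size, dtype=np.int64)
            else:
                p = self.shape / (self.shape + m)
                gens = 1 + rng.negative_binomial(self.shape, p, size=size)
        return np.minimum(gens, horizon)


#: Default per-class sterility models (horizon 21 unless noted).  Means are
#: placed well inside the class-defining thresholds so that classification of
#: a generated line recovers its latent class with high probability.
DEFAULT_STERILITY_MODELS: dict[str, ClassSterilityModel] = {
    # all replicates sterile, mean ~6 << 10, max < 15 almost surely
    "strong": ClassSterilityModel(1.0, mean_generation=6.0, shape=50.0),
    # all replicates sterile by 21, mean ~13 < 16
    "moderate": ClassSterilityModel(1.0, mean_generation=13.0, shape=80.0),
    # ~90% of replicates sterile (>= 2/3 rule), late onset so the all-sterile
    # subset rarely has mean < 16
    "weak": ClassSterilityModel(0.9, mean_generation=19.0, shape=200.0),
    # sporadic non-heritable failures, matching the ~5% replicate failure
    # rate seen in ancestral pseudolines
    "wild_type": ClassSterilityModel(0.05, mean_generation=12.0, shape=2.0),
    # heat-sensitive sterile: all replicates fail in the first generation
    "ts_sterile": ClassSterilityModel(1.0, family="degenerate", low=1),
    # sickly lines; failures annotated as unrelated to Mrt
    "low_fitness": ClassSterilityModel(
        0.85, mean_generation=5.0, shape=2.0, failure_mode=FailureMode.NON_MRT_FAILURE.value
    ),
}

_CLASS_ORDER = ["strong", "moderate", "weak", "wild_type", "ts_sterile", "low_fitness"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic assay: design, class mixture, models, seed."""

    design: AssayDesign
    mixture: dict[str, float]
    models: dict[str, ClassSterilityModel] = field(
        default_factory=lambda: dict(DEFAULT_STERILITY_MODELS)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.mixture:
            raise ConfigurationError("mixture must not be empty")
        unknown = set(self.mixture) - set(_CLASS_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown mixture classes: {sorted(unknown)}")
        if any(p < 0 for p in self.mixture.values()):
            raise ConfigurationError("mixture proportions must be >= 0")
        if not math.isclose(sum(self.mixture.values()), 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"mixture proportions must sum to 1 (got {sum(self.mixture.values())})"
            )
        missing = [c for c in self.mixture if c not in self.models]
        if missing:
            raise ConfigurationError(f"no sterility model for classes: {missing}")


def _root_seed(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def draw_line_classes(config: SyntheticConfig) -> list[str]:
    """Latent class of every line, deterministic in the seed.

    Uses each line's own substream, so the class of line ``i`` does not
    depend on ``n_lines``.
    """
    classes = [c for c in _CLASS_ORDER if c in config.mixture]
    probs = np.array([config.mixture[c] for c in classes])
    cum = np.cumsum(probs)
    out = []
    for child in _root_seed(config.seed).spawn(config.design.n_lines):
        rng = np.random.default_rng(child)
        u = rng.random()
        out.append(classes[int(np.searchsorted(cum, u, side="right").clip(0, len(classes) - 1))])
    return out


def _sample_line(
    rng: np.random.Generator, model: ClassSterilityModel, reps: int, horizon: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    sterile = rng.random(reps) < model.sterility_prob
    gens = np.where(sterile, model.sample(rng, reps, horizon), 0)
    modes = [model.failure_mode if s else FailureMode.NONE.value for s in sterile]
    return gens, ~sterile, modes


def _assemble_table(
    line_ids, rep_ids, gens, censored, modes
) -> pd.DataFrame:
    gens = np.asarray(gens)
    censored = np.asarray(censored, dtype=bool)
    table = pd.DataFrame(
        {
            "line_id": line_ids,
            "replicate_id": rep_ids,
            "sterile_generation": pd.array(
                np.where(censored, 0, gens), dtype="Int64"
            ),
            "censored": censored.astype(int),
            "failure_mode": modes,
        }
    )
    table.loc[table["censored"] == 1, "sterile_generation"] = pd.NA
    return table[TABLE_COLUMNS]


def generate_assay_table(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a tidy assay table (one row per line x replicate).

    Columns: ``line_id, replicate_id, sterile_generation, censored,
    failure_mode`` with ``censored`` in {0, 1} and ``sterile_generation``
    missing when censored.  The latent classes behind the table are
    available via :func:`draw_line_classes` with the same config.
    """
    design = config.design
    classes = [c for c in _CLASS_ORDER if c in config.mixture]
    probs = np.array([config.mixture[c] for c in classes])
    cum = np.cumsum(probs)

    line_ids, rep_ids, all_gens, all_cens, all_modes = [], [], [], [], []
    width = max(4, len(str(design.n_lines)))
    for i, child in enumerate(_root_seed(config.seed).spawn(design.n_lines)):
        rng = np.random.default_rng(child)
        u = rng.random()  # class draw first: keeps draw_line_classes in sync
        cls = classes[int(np.searchsorted(cum, u, side="right").clip(0, len(classes) - 1))]
        gens, cens, modes = _sample_line(
            rng, config.models[cls], design.reps_per_line, design.assay_generations
        )
        lid = f"L{i + 1:0{width}d}"
        line_ids.extend([lid] * design.reps_per_line)
        rep_ids.extend(f"r{j + 1:02d}" for j in range(design.reps_per_line))
        all_gens.append(gens)
        all_cens.append(cens)
        all_modes.extend(modes)
    return _assemble_table(
        line_ids, rep_ids, np.concatenate(all_gens), np.concatenate(all_cens), all_modes
    )


def generate_ma_experiment(
    n_lines: int,
    t_gens: int,
    U: float,
    design: AssayDesign | None = None,
    seed=None,
    models: dict[str, ClassSterilityModel] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Simulate a full MA experiment followed by its Mrt assay.

    Each line independently accumulates Mrt mutations over ``t_gens``
    generations of single-descent propagation: mutations arise in the
    diploid genome as a Poisson process at rate ``2U`` per generation and
    each new heterozygous mutation survives drift to fixation with
    probability 1/2 (see :func:`mrtline.popgen_sim.ma_transmission`), so
    surviving mutations are Poisson with mean ``U * t_gens`` per line.
    Lines carrying at least one surviving mutation express the strong-Mrt
    sterility model in the assay; the rest are wild type.

    Returns the assay table and ``k_true``, the number of mutant lines.
    """
    if U < 0:
        raise ConfigurationError("U must be >= 0")
    if n_lines < 1 or t_gens < 1:
        raise ConfigurationError("n_lines and t_gens must be >= 1")
    if design is None:
        design = AssayDesign(n_lines, 10, FULL_ASSAY_HORIZON, "simulated MA")
    models = dict(DEFAULT_STERILITY_MODELS) if models is None else models

    line_ids, rep_ids, all_gens, all_cens, all_modes = [], [], [], [], []
    k_true = 0
    width = max(4, len(str(n_lines)))
    for i, child in enumerate(_root_seed(seed).spawn(n_lines)):
        rng = np.random.default_rng(child)
        arising = rng.poisson(2.0 * U * t_gens)
        surviving = rng.binomial(arising, 0.5) if arising else 0
        mutant = surviving >= 1
        k_true += int(mutant)
        model = models["strong"] if mutant else models["wild_type"]
        gens, cens, modes = _sample_line(
            rng, model, design.reps_per_line, design.assay_generations
        )
        lid = f"L{i + 1:0{width}d}"
        line_ids.extend([lid] * design.reps_per_line)
        rep_ids.extend(f"r{j + 1:02d}" for j in range(design.reps_per_line))
        all_gens.append(gens)
        all_cens.append(cens)
        all_modes.extend(modes)
    table = _assemble_table(
        line_ids, rep_ids, np.concatenate(all_gens), np.concatenate(all_cens), all_modes
    )
    return table, k_true
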