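from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrtline.phenotyping import LineAssay, ReplicateOutcome


def make_line(
    sterile_gens,
    n_censored: int = 0,
    horizon: int = 21,
    line_id: str = "L1",
    non_mrt: int = 0,
):
    """Build a LineAssay from sterile generations plus censored replicates.

    The first ``non_mrt`` sterile replicates are annotated as non-Mrt
    failures (low-fitness deaths).
    """
    outcomes = []
    for i, g in enumerate(sterile_gens):
        mode = "non_mrt_failure" if i < non_mrt else "mrt_sterile"
        outcomes.append(
            ReplicateOutcome(line_id, f"r{i + 1:02d}", int(g), False, mode)
        )
    for j in range(n_censored):
        outcomes.append(
            ReplicateOutcome(line_id, f"r{len(sterile_gens) + j + 1:02d}", None, True, "none")
        )
    return LineAssay(line_id=line_id, outcomes=outcomes, horizon=horizon)


def table_from_lines(lines: dict[str, tuple[list[int], int]], horizon: int = 21) -> pd.DataFrame:
    """Tidy assay table from {line_id: (sterile_gens, n_censored)}."""
    rows = []
    for line_id, (gens, n_cens) in lines.items():
        for i, g in enumerate(gens):
            rows.append((line_id, f"r{i + 1:02d}", g, 0, "mrt_sterile"))
        for j in range(n_cens):
            rows.append((line_id, f"r{len(gens) + j + 1:02d}", None, 1, "none"))
    return pd.DataFrame(
        rows, columns=["line_id", "replicate_id", "sterile_generation", "censored", "failure_mode"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220321)
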