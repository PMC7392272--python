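"""Shared builders for the test suite: tiny matrices, designs, status tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from regenpath.expression import DESIGN_GROUPS, CountMatrix


def design_frame(n_reps: int = 3) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"{c}_{t}_r{r}",
            "condition": c,
            "timepoint": t,
            "replicate": r,
        }
        for c, t in DESIGN_GROUPS
        for r in range(1, n_reps + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def make_matrix(genes: dict[str, list[int]], n_reps: int = 3) -> CountMatrix:
    """CountMatrix from per-gene count rows ordered by group x replicate.

    Row order: CTL-P1 r1..rN, CTL-P7, CTL-P28, MI-P7, MI-P28.
    """
    d = design_frame(n_reps)
    counts = pd.DataFrame.from_dict(
        genes, orient="index", columns=list(d.index)
    )
    return CountMatrix.from_frames(counts, d)


def random_matrix(
    rng: np.random.Generator, n_genes: int = 12, n_reps: int = 3,
    low: int = 1, high: int = 2000,
) -> CountMatrix:
    d = design_frame(n_reps)
    counts = pd.DataFrame(
        rng.integers(low, high, size=(n_genes, len(d))),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=list(d.index),
    )
    return CountMatrix.from_frames(counts, d)


def status_frame(early=(), late=(), down=()) -> pd.DataFrame:
    genes = sorted(set(early) | set(late) | set(down))
    return pd.DataFrame(
        {
            "gene_id": genes,
            "early_up": [g in set(early) for g in genes],
            "late_up": [g in set(late) for g in genes],
            "late_down": [g in set(down) for g in genes],
        }
    ).set_index("gene_id")


def sums_frame(gene: str, groups: dict[tuple[str, str], tuple[float, float]],
               n: int = 3) -> pd.DataFrame:
    """Hand-built group-summary table for one gene: {(cond, tp): (mean, sem)}."""
    rows = [
        {
            "gene_id": gene,
            "condition": c,
            "timepoint": t,
            "n": n,
            "raw_total": 0,
            "mean_norm": mean,
            "sem_norm": sem,
        }
        for (c, t), (mean, sem) in groups.items()
    ]
    return pd.DataFrame(rows).set_index(["gene_id", "condition", "timepoint"])
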