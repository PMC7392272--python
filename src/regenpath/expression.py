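"""Count-matrix ingestion, normalization, and per-group expression summaries.

This module covers the pre-model half of a bulk RNA-seq differential
expression workflow for the five-group neonatal infarction design
(CTL-P1, CTL-P7, CTL-P28, MI-P7, MI-P28):

* reading a raw gene x sample count matrix (TSV) plus a sample design table,
* median-of-ratios size factors (the normalization step of the standard
  negative-binomial DE workflow; the GLM itself is out of scope here),
* per condition x timepoint group means with SEM error-bar half-widths,
* MI-vs-CTL fold changes with a configurable pseudocount.

The in-memory containers are thin dataclasses around pandas frames so that
downstream modules can index by gene, sample, and group without re-parsing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

CONDITIONS = ("CTL", "MI")
TIMEPOINTS = ("P1", "P7", "P28")

#: The five condition x timepoint groups of the study design.  Infarction is
#: induced at P1 and tissue collected at P7/P28, so there is no MI-P1
#: expression group.
DESIGN_GROUPS = (
    ("CTL", "P1"),
    ("CTL", "P7"),
    ("CTL", "P28"),
    ("MI", "P7"),
    ("MI", "P28"),
)


class FormatError(ValueError):
    """An input file violates the expected tabular or JSON contract."""


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer counts (genes x samples) with the sample design.

    Attributes
    ----------
    counts:
        Integer DataFrame, index = gene IDs, columns = sample IDs.
    design:
        DataFrame indexed by sample ID with columns ``condition``
        (``MI``/``CTL``), ``timepoint`` (``P1``/``P7``/``P28``) and
        ``replicate`` (positive integer).
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, condition: str, timepoint: str) -> list[str]:
        """Sample IDs belonging to one condition x timepoint group."""
        mask = (self.design["condition"] == condition) & (
            self.design["timepoint"] == timepoint
        )
        return list(self.design.index[mask])

    def groups_present(self) -> list[tuple[str, str]]:
        return [g for g in DESIGN_GROUPS if self.samples_in_group(*g)]

    @staticmethod
    def from_frames(counts: pd.DataFrame, design: pd.DataFrame) -> "CountMatrix":
        """Validate and assemble a :class:`CountMatrix` from raw frames."""
        counts = counts.copy()
        design = design.copy()
        _validate_design(design)
        _validate_counts(counts, design)
        # align design row order to matrix column order; normalize axis names
        design = design.loc[counts.columns]
        counts.index.name = "gene_id"
        counts.columns.name = None
        design.index.name = "sample_id"
        return CountMatrix(counts=counts.astype(np.int64), design=design)


def _validate_design(design: pd.DataFrame) -> None:
    required = {"condition", "timepoint", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    if design.index.duplicated().any():
        dup = design.index[design.index.duplicated()][0]
        raise FormatError(f"duplicate sample_id in design: {dup!r}")
    bad_cond = set(design["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise FormatError(f"unknown condition value(s): {sorted(bad_cond)}")
    bad_tp = set(design["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise FormatError(f"unknown timepoint value(s): {sorted(bad_tp)}")
    mi_p1 = design[(design["condition"] == "MI") & (design["timepoint"] == "P1")]
    if len(mi_p1):
        raise FormatError(
            "MI samples exist only at P7 and P28 (infarction is induced at P1, "
            f"collected later); offending sample(s): {list(mi_p1.index)}"
        )
    rep = pd.to_numeric(design["replicate"], errors="coerce")
    if rep.isna().any() or (rep < 1).any() or (rep != rep.astype(int)).any():
        raise FormatError("replicate must be a positive integer for every sample")


def _validate_counts(counts: pd.DataFrame, design: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise FormatError(f"duplicate gene ID in counts: {dup!r}")
    extra = [s for s in counts.columns if s not in design.index]
    if extra:
        raise FormatError(f"sample column {extra[0]!r} absent from design table")
    absent = [s for s in design.index if s not in counts.columns]
    if absent:
        raise FormatError(f"design sample {absent[0]!r} absent from count matrix")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        coerced = counts.apply(pd.to_numeric, errors="coerce")
        if coerced.isna().any().any():
            g, s = _first_bad_cell(coerced.isna())
            raise FormatError(f"non-numeric count for gene {g!r}, sample {s!r}")
        arr = coerced.to_numpy()
        counts.loc[:, :] = arr
    if (arr < 0).any():
        g, s = _first_bad_cell(counts < 0)
        raise FormatError(f"negative count for gene {g!r}, sample {s!r}")
    if not np.allclose(arr, np.round(arr)):
        g, s = _first_bad_cell(counts != np.round(counts))
        raise FormatError(f"non-integer count for gene {g!r}, sample {s!r}")


def _first_bad_cell(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, sample = stacked[stacked].index[0]
    return str(gene), str(sample)


def read_counts(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a counts TSV and design TSV into a validated :class:`CountMatrix`.

    The counts file is tab-separated with gene IDs in the first column and
    sample IDs in the header; the design file has columns ``sample_id``,
    ``condition``, ``timepoint``, ``replicate``.
    """
    counts_path, design_path = Path(counts_path), Path(design_path)
    if not counts_path.exists():
        raise FileNotFoundError(f"counts file not found: {counts_path}")
    if not design_path.exists():
        raise FileNotFoundError(f"design file not found: {design_path}")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, dtype=str)
    try:
        counts = counts.apply(pd.to_numeric)
    except (ValueError, TypeError):
        coerced = counts.apply(pd.to_numeric, errors="coerce")
        g, s = _first_bad_cell(coerced.isna())
        raise FormatError(f"non-numeric count for gene {g!r}, sample {s!r}") from None
    design = pd.read_csv(design_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in design.columns:
        raise FormatError("design table must have a sample_id column")
    design = design.set_index("sample_id")
    return CountMatrix.from_frames(counts, design)


def write_counts(m: CountMatrix, counts_path: str | Path, design_path: str | Path) -> None:
    """Write the matrix and design back to the TSV dialect ``read_counts`` accepts."""
    m.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    m.design.to_csv(design_path, sep="\t", index_label="sample_id")


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, the factor is the median over reference genes g of
    ``count(g, j) / geomean_over_samples(count(g, .))`` where reference genes
    are those with strictly positive counts in every sample.  Dividing raw
    counts by the factors yields normalized counts.  The geometric-mean-1
    rescaling removes the overall scale indeterminacy.
    """
    arr = m.counts.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; the "
            "median-of-ratios reference set is empty (add a pseudocount or "
            "use a matrix with more uniformly detected genes)"
        )
    logs = np.log(arr[ref])
    log_geomean = logs.mean(axis=1)
    ratios = np.exp(logs - log_geomean[:, None])
    s = np.median(ratios, axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=m.counts.columns, name="size_factor")


def normalized_counts(m: CountMatrix, factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """Raw counts divided column-wise by the size factors."""
    if factors is None:
        factors = size_factors(m)
    return m.counts.div(factors, axis=1)


def summarize_groups(
    m: CountMatrix, factors: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Per-gene, per-group normalized summaries.

    Returns a DataFrame indexed by ``(gene_id, condition, timepoint)`` with
    columns ``n`` (replicates), ``raw_total`` (sum of raw counts in the
    group), ``mean_norm`` (arithmetic mean of normalized counts) and
    ``sem_norm`` (sample SD / sqrt(n); 0 when n == 1).  SEM is the error-bar
    half-width convention used throughout the pipeline.
    """
    if factors is None:
        factors = size_factors(m)
    norm = normalized_counts(m, factors)
    pieces = []
    for cond, tp in DESIGN_GROUPS:
        samples = m.samples_in_group(cond, tp)
        if not samples:
            continue
        sub = norm[samples]
        n = len(samples)
        mean = sub.mean(axis=1)
        if n > 1:
            sem = sub.std(axis=1, ddof=1) / math.sqrt(n)
        else:
            sem = pd.Series(0.0, index=sub.index)
        piece = pd.DataFrame(
            {
                "gene_id": sub.index,
                "condition": cond,
                "timepoint": tp,
                "n": n,
                "raw_total": m.counts[samples].sum(axis=1).to_numpy(),
                "mean_norm": mean.to_numpy(),
                "sem_norm": sem.to_numpy(),
            }
        )
        pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    return out.set_index(["gene_id", "condition", "timepoint"]).sort_index()


@dataclass(frozen=True)
class FoldChangeRecord:
    """MI-over-CTL fold change at one timepoint for one gene."""

    gene_id: str
    timepoint: str
    log2fc: float
    fold: float
    p_concordance: Optional[float] = None  # None == not applicable


def fold_change(
    sums: pd.DataFrame,
    gene: str,
    timepoint: str,
    pseudocount: float = 0.5,
    p_concordance: Optional[float] = None,
) -> FoldChangeRecord:
    """Pseudocount-adjusted MI/CTL fold change from group summaries.

    ``fold = (mean_MI + pc) / (mean_CTL + pc)``; the pseudocount keeps the
    ratio finite for genes silent in controls.
    """
    if timepoint not in ("P7", "P28"):
        raise ValueError(f"fold change defined at P7/P28 only, got {timepoint!r}")
    try:
        mi = sums.loc[(gene, "MI", timepoint), "mean_norm"]
        ctl = sums.loc[(gene, "CTL", timepoint), "mean_norm"]
    except KeyError:
        raise KeyError(
            f"missing MI or CTL summary for gene {gene!r} at {timepoint}"
        ) from None
    fold = (mi + pseudocount) / (ctl + pseudocount)
    return FoldChangeRecord(
        gene_id=gene,
        timepoint=timepoint,
        log2fc=math.log2(fold),
        fold=fold,
        p_concordance=p_concordance,
    )


def group_values(
    m: CountMatrix,
    gene: str,
    condition: str,
    timepoint: str,
    factors: Optional[pd.Series] = None,
) -> list[float]:
    """Per-replicate normalized values for one gene in one group."""
    if gene not in m.counts.index:
        raise KeyError(f"unknown gene: {gene!r}")
    samples = m.samples_in_group(condition, timepoint)
    if factors is None:
        factors = size_factors(m)
    return [m.counts.loc[gene, s] / factors[s] for s in samples]
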