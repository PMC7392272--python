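"""End-to-end pipeline runs: counts -> gene statuses -> pathway calls -> report.

A run is driven by a :class:`RunConfig` holding either input paths (counts
TSV + design TSV, plus an optional pathway catalog) or a simulation block,
never both.  Outputs are written to a fixed layout in the output directory
with deterministic (sorted) row order so that reruns with the same
configuration and seed reproduce every file:

```
size_factors.tsv       per-sample median-of-ratios factors
group_summaries.tsv    gene x group normalized mean / SEM / raw totals
fold_changes.tsv       MI-vs-CTL log2 fold changes at P7 and P28
gene_status.tsv        classifier flags per gene
status_summary.json    category counts
pathway_calls.json     per-pathway chain calls
catalog_summary.tsv    one row per catalog entry
run_summary.json       headline counts, config hash, versions, seed
truth.json             (simulation runs only) planted ground truth
```
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .caller import CatalogReport, call_catalog
from .classify import ClassifierConfig, classify_all, status_summary
from .expression import (
    CountMatrix,
    fold_change,
    read_counts,
    size_factors,
    summarize_groups,
    write_counts,
)
from .pathway import PathwayCatalog, load_catalog, load_packaged_catalog
from .simulate import SimConfig, SyntheticTruth, generate, simconfig_from_dict

log = logging.getLogger("regenpath")


@dataclass(frozen=True)
class RunConfig:
    counts: Optional[Path] = None
    design: Optional[Path] = None
    catalog: Optional[Path] = None  # None -> packaged catalog
    simulate: Optional[SimConfig] = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    output_dir: Path = Path("regenpath_out")

    def __post_init__(self) -> None:
        has_inputs = self.counts is not None or self.design is not None
        has_sim = self.simulate is not None
        if has_inputs and has_sim:
            raise ValueError(
                "config must have exactly one of input paths or a simulate "
                "block, not both"
            )
        if not has_inputs and not has_sim:
            raise ValueError("config needs either counts+design paths or a "
                             "simulate block")
        if has_inputs and (self.counts is None or self.design is None):
            raise ValueError("counts and design paths must be given together")


def runconfig_from_dict(data: dict) -> RunConfig:
    inputs = data.get("inputs") or {}
    sim = data.get("simulate")
    classifier = ClassifierConfig(**(data.get("classifier") or {}))
    return RunConfig(
        counts=Path(inputs["counts"]) if "counts" in inputs else None,
        design=Path(inputs["design"]) if "design" in inputs else None,
        catalog=Path(inputs["catalog"]) if "catalog" in inputs else None,
        simulate=simconfig_from_dict(sim) if sim is not None else None,
        classifier=classifier,
        output_dir=Path(data.get("output_dir", "regenpath_out")),
    )


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o))

    fields = dataclasses.asdict(cfg)
    fields.pop("output_dir", None)  # same analysis config -> same hash
    payload = json.dumps(fields, default=str, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fold_change_table(m: CountMatrix, sums: pd.DataFrame,
                       statuses: pd.DataFrame, pseudocount: float) -> pd.DataFrame:
    rows = []
    for gene in sorted(m.gene_ids):
        for tp, fc_col, p_col in (
            ("P7", "log2fc_P7", "p_concordance_P7"),
            ("P28", "log2fc_P28", None),
        ):
            try:
                rec = fold_change(sums, gene, tp, pseudocount)
            except KeyError:
                continue
            p = statuses.loc[gene, p_col] if p_col else np.nan
            rows.append(
                {
                    "gene_id": gene,
                    "timepoint": tp,
                    "log2fc": rec.log2fc,
                    "fold": rec.fold,
                    "p_concordance": p,
                }
            )
    return pd.DataFrame(rows)


def run(cfg: RunConfig) -> dict:
    """Execute the pipeline; returns the run-summary dict (also written)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth: Optional[SyntheticTruth] = None
    if cfg.simulate is not None:
        log.info("simulating counts (seed=%d)", cfg.simulate.seed)
        m, truth = generate(cfg.simulate)
        write_counts(m, out / "counts.tsv", out / "design.tsv")
        (out / "truth.json").write_text(
            json.dumps(truth.to_dict(), indent=2, default=bool) + "\n"
        )
    else:
        log.info("reading counts from %s", cfg.counts)
        m = read_counts(cfg.counts, cfg.design)

    factors = size_factors(m)
    factors.sort_index().to_csv(out / "size_factors.tsv", sep="\t",
                                index_label="sample_id")
    sums = summarize_groups(m, factors)
    sums.sort_index().to_csv(out / "group_summaries.tsv", sep="\t")

    statuses = classify_all(m, cfg.classifier)
    statuses.to_csv(out / "gene_status.tsv", sep="\t")
    counts_summary = status_summary(statuses)
    (out / "status_summary.json").write_text(
        json.dumps(counts_summary, indent=2) + "\n"
    )

    fc = _fold_change_table(m, sums, statuses, cfg.classifier.pseudocount)
    fc.to_csv(out / "fold_changes.tsv", sep="\t", index=False)

    catalog: PathwayCatalog = (
        load_catalog(cfg.catalog) if cfg.catalog else load_packaged_catalog()
    )
    report: CatalogReport = call_catalog(catalog, statuses)
    (out / "pathway_calls.json").write_text(
        json.dumps([c.to_dict() for c in report.calls], indent=2) + "\n"
    )
    report.to_frame().to_csv(out / "catalog_summary.tsv", sep="\t")

    summary = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.simulate.seed if cfg.simulate else None,
        "genes": counts_summary,
        "pathways": report.summary(),
    }
    if truth is not None:
        summary["truth_agreement"] = truth_agreement(statuses, truth, report)
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    log.info(
        "done: %d early / %d late / %d persistent genes; %d of %d pathways "
        "comprehensively upregulated",
        counts_summary["n_early_up"],
        counts_summary["n_late_up"],
        counts_summary["n_persistent"],
        report.n_comprehensive,
        report.n_catalog,
    )
    return summary


def truth_agreement(
    statuses: pd.DataFrame, truth: SyntheticTruth, report: Optional[CatalogReport] = None
) -> dict:
    """Compare classifier output (and pathway calls) with planted truth."""
    joined = statuses.join(truth.genes, how="inner")
    agree = {
        flag: float(
            (joined[flag] == joined[f"expected_{flag}"]).mean()
        )
        for flag in ("passes_abundance", "early_up", "late_up")
    }
    pos = joined["expected_early_up"]
    called = joined["early_up"]
    sens = float(called[pos].mean()) if pos.any() else float("nan")
    spec = float((~called[~pos]).mean()) if (~pos).any() else float("nan")
    out = {
        "fraction_agree": agree,
        "early_sensitivity": sens,
        "early_specificity": spec,
        "n_genes_compared": int(len(joined)),
    }
    if report is not None and truth.pathways:
        calls = {c.pathway_id: c.comprehensive for c in report.calls}
        out["pathway_calls_match"] = {
            pid: calls.get(pid) == expected
            for pid, expected in truth.pathways.items()
        }
    return out
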