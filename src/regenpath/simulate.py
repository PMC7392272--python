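"""Synthetic count matrices with planted ground truth.

The generator emulates the five-group neonatal-infarction design — three
biological replicates per condition x timepoint group (CTL-P1, CTL-P7,
CTL-P28, MI-P7, MI-P28) — with negative-binomial counts parameterized by
(mean, size), per-gene log-normal baselines, and optional per-sample
library-size multipliers so that normalization is actually exercised.

Planted structure:

* *positive* genes carry a >= 2-fold MI effect at P7 (and at P28 when
  ``persists``); their control expression declines two-fold from P1 to P7,
  the developmental profile the early-upregulation filter expects;
* *decoy* genes each violate exactly one filtering criterion in
  expectation: ``low_abundance`` (total raw counts far below the 200
  floor), ``overlapping_bars`` (a real fold effect drowned in inflated
  dispersion so SEM intervals overlap), ``control_drift`` (control
  expression doubles from P1 to P7), ``subthreshold_fold`` (MI effect of
  only 1.5-fold);
* *pathway scenarios* plant one member gene per node along a chain of a
  packaged pathway graph, optionally leaving one node at baseline to break
  the chain.

A noise-free switch emits exact group means rounded to integers (library
multipliers off), which makes classifier recovery exact and serves as the
pipeline's end-to-end smoke test.  All randomness flows from the single
seed; the same configuration and seed reproduce the matrix byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .classify import ClassifierConfig
from .expression import DESIGN_GROUPS, CountMatrix
from .pathway import PathwayGraph, load_packaged_pathway

DECOY_KINDS = (
    "low_abundance",
    "overlapping_bars",
    "control_drift",
    "subthreshold_fold",
)

#: baseline mean forced for low-abundance decoys (expected raw total ~ 80,
#: far below the 200-count floor)
LOW_ABUNDANCE_BASELINE = 3.0
#: negative-binomial size for overlapping-bars decoys (heavily overdispersed)
OVERLAP_DISPERSION = 0.3
#: MI fold for decoys that must pass the fold criterion robustly
DECOY_FOLD = 4.0
SUBTHRESHOLD_FOLD = 1.5


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    fold: float = 4.0
    persists: bool = False

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError(f"planted fold must be >= 1, got {self.fold}")


@dataclass(frozen=True)
class Decoy:
    gene_id: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in DECOY_KINDS:
            raise ValueError(f"unknown decoy kind {self.kind!r}")


@dataclass(frozen=True)
class PathwayScenario:
    pathway_id: str
    satisfied: bool = True
    break_node: Optional[str] = None


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 1000
    n_replicates: int = 3
    #: (location, scale) of the per-gene log-normal baseline expression
    baseline_log_mean: tuple[float, float] = (5.5, 1.0)
    #: negative-binomial size parameter (larger = less overdispersed)
    dispersion: float = 10.0
    planted_early: tuple[PlantedGene, ...] = ()
    planted_decoys: tuple[Decoy, ...] = ()
    pathway_scenarios: tuple[PathwayScenario, ...] = ()
    seed: int = 0
    noise_free: bool = False
    #: per-sample library-size multipliers drawn log-uniformly from this
    #: range; None disables them (they are always off in noise-free mode)
    library_size_range: Optional[tuple[float, float]] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        ids = [p.gene_id for p in self.planted_early] + [
            d.gene_id for d in self.planted_decoys
        ]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"planted gene IDs must be distinct; duplicate {dup!r}")
        if len(ids) > self.n_genes:
            raise ValueError(
                f"{len(ids)} planted genes exceed n_genes={self.n_genes}"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Expected classifier outcomes and pathway calls for a simulated matrix."""

    genes: pd.DataFrame  # index gene_id; expected_* boolean columns
    pathways: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genes": self.genes.reset_index().to_dict(orient="records"),
            "pathways": dict(self.pathways),
        }


def _lexicographic_chains(g: PathwayGraph) -> list[tuple[str, ...]]:
    digraph = g.to_networkx()
    chains = []
    for init in g.initiators():
        for eff in g.effectors():
            chains.extend(
                tuple(p) for p in nx.all_simple_paths(digraph, init, eff)
            )
    return sorted(chains)


def plant_pathway_scenario(
    cfg: SimConfig, fixture: PathwayGraph, satisfied: bool = True,
    break_node: Optional[str] = None,
) -> SimConfig:
    """Augment a config with planted genes realizing a pathway scenario.

    For ``satisfied``, every node on the lexicographically first
    initiator-to-effector chain gets one member planted (fold 4,
    persistent); with a ``break_node``, the first chain through that node is
    planted except the node itself, whose members stay at baseline.
    """
    scenario = PathwayScenario(
        pathway_id=fixture.pathway_id, satisfied=satisfied, break_node=break_node
    )
    planted = _plant_for_scenario(cfg, fixture, scenario)
    return replace(
        cfg,
        planted_early=cfg.planted_early + tuple(planted),
        pathway_scenarios=cfg.pathway_scenarios + (scenario,),
    )


def _plant_for_scenario(
    cfg: SimConfig, fixture: PathwayGraph, scenario: PathwayScenario
) -> list[PlantedGene]:
    chains = _lexicographic_chains(fixture)
    if not chains:
        raise ValueError(
            f"pathway {fixture.pathway_id!r} has no initiator-to-effector chain"
        )
    if scenario.satisfied:
        chain = chains[0]
        skip: set[str] = set()
    else:
        if scenario.break_node is None:
            raise ValueError("unsatisfied scenario requires a break_node")
        if scenario.break_node not in fixture.nodes:
            raise ValueError(
                f"break_node {scenario.break_node!r} not in pathway "
                f"{fixture.pathway_id!r}"
            )
        through = [c for c in chains if scenario.break_node in c]
        if not through:
            raise ValueError(
                f"no initiator-to-effector chain passes through "
                f"{scenario.break_node!r}"
            )
        chain = through[0]
        skip = {scenario.break_node}
    already = {p.gene_id for p in cfg.planted_early} | {
        d.gene_id for d in cfg.planted_decoys
    }
    new: list[PlantedGene] = []
    for nid in chain:
        if nid in skip:
            continue
        members = fixture.nodes[nid].members
        if any(m in already for m in members):
            continue  # node already satisfied by an earlier scenario
        new.append(PlantedGene(gene_id=members[0], fold=4.0, persists=True))
        already.add(members[0])
    return new


def _resolve_scenarios(cfg: SimConfig) -> SimConfig:
    """Ensure every configured scenario has its genes planted (idempotent)."""
    out = cfg
    for scenario in cfg.pathway_scenarios:
        fixture = load_packaged_pathway(scenario.pathway_id)
        planted = _plant_for_scenario(out, fixture, scenario)
        if planted:
            out = replace(out, planted_early=out.planted_early + tuple(planted))
    return out


def _sample_table(n_replicates: int) -> pd.DataFrame:
    rows = []
    for cond, tp in DESIGN_GROUPS:
        for r in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{cond}_{tp}_r{r}",
                    "condition": cond,
                    "timepoint": tp,
                    "replicate": r,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _group_means(
    baseline: float, fold_p7: float, fold_p28: float, control_profile: str
) -> dict[tuple[str, str], float]:
    """Mean model for one gene.

    ``control_profile`` is ``flat`` (all control groups at baseline),
    ``declining`` (control halves from P1 to P7 — the early-postnatal
    profile), or ``rising`` (control doubles from P1 to P7 — drift decoy).
    """
    b = baseline
    if control_profile == "flat":
        ctl = {"P1": b, "P7": b, "P28": b}
    elif control_profile == "declining":
        ctl = {"P1": 2 * b, "P7": b, "P28": b}
    elif control_profile == "rising":
        ctl = {"P1": b, "P7": 2 * b, "P28": 2 * b}
    else:  # pragma: no cover
        raise ValueError(control_profile)
    return {
        ("CTL", "P1"): ctl["P1"],
        ("CTL", "P7"): ctl["P7"],
        ("CTL", "P28"): ctl["P28"],
        ("MI", "P7"): fold_p7 * ctl["P7"],
        ("MI", "P28"): fold_p28 * ctl["P28"],
    }


def generate(cfg: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix and its ground-truth table from a configuration."""
    cfg = _resolve_scenarios(cfg)
    rng = np.random.default_rng(cfg.seed)
    design = _sample_table(cfg.n_replicates)
    samples = list(design.index)

    planted_ids = [p.gene_id for p in cfg.planted_early]
    decoy_ids = [d.gene_id for d in cfg.planted_decoys]
    n_background = cfg.n_genes - len(planted_ids) - len(decoy_ids)
    background_ids = [f"SIMG{i:05d}" for i in range(1, n_background + 1)]
    clash = (set(planted_ids) | set(decoy_ids)) & set(background_ids)
    if clash:
        raise ValueError(f"planted gene ID collides with background ID: {clash}")
    gene_ids = planted_ids + decoy_ids + background_ids

    baselines = rng.lognormal(
        mean=cfg.baseline_log_mean[0],
        sigma=cfg.baseline_log_mean[1],
        size=cfg.n_genes,
    )

    mean_rows = []
    gene_dispersion = np.full(cfg.n_genes, cfg.dispersion)
    meta = []
    for i, gid in enumerate(gene_ids):
        b = baselines[i]
        if i < len(planted_ids):
            p = cfg.planted_early[i]
            means = _group_means(
                b, p.fold, p.fold if p.persists else 1.0, "declining"
            )
            meta.append((gid, "planted", None, True, p.persists))
        elif i < len(planted_ids) + len(decoy_ids):
            d = cfg.planted_decoys[i - len(planted_ids)]
            if d.kind == "low_abundance":
                b = LOW_ABUNDANCE_BASELINE
                means = _group_means(b, DECOY_FOLD, 1.0, "declining")
            elif d.kind == "overlapping_bars":
                means = _group_means(b, DECOY_FOLD, 1.0, "declining")
                gene_dispersion[i] = OVERLAP_DISPERSION
            elif d.kind == "control_drift":
                means = _group_means(b, DECOY_FOLD, 1.0, "rising")
            else:  # subthreshold_fold
                means = _group_means(b, SUBTHRESHOLD_FOLD, 1.0, "declining")
            meta.append((gid, "decoy", d.kind, False, False))
        else:
            means = _group_means(b, 1.0, 1.0, "flat")
            meta.append((gid, "background", None, False, False))
        mean_rows.append(
            [means[(design.loc[s, "condition"], design.loc[s, "timepoint"])]
             for s in samples]
        )
    mu = np.asarray(mean_rows)

    if cfg.noise_free or cfg.library_size_range is None:
        multipliers = np.ones(len(samples))
    else:
        lo, hi = cfg.library_size_range
        multipliers = np.exp(
            rng.uniform(math.log(lo), math.log(hi), size=len(samples))
        )
    mu_scaled = mu * multipliers[None, :]

    if cfg.noise_free:
        counts = np.rint(mu_scaled).astype(np.int64)
    else:
        size = gene_dispersion[:, None]
        p = size / (size + np.maximum(mu_scaled, 1e-12))
        counts = rng.negative_binomial(size, p).astype(np.int64)

    matrix = CountMatrix.from_frames(
        pd.DataFrame(counts, index=gene_ids, columns=samples), design
    )
    truth = _build_truth(cfg, matrix, meta, mu_scaled)
    return matrix, truth


def _build_truth(
    cfg: SimConfig,
    matrix: CountMatrix,
    meta: Sequence[tuple],
    mu_scaled: np.ndarray,
) -> SyntheticTruth:
    rules = ClassifierConfig()
    gene_ids = [m[0] for m in meta]
    if cfg.noise_free:
        # deterministic: apply the filtering rules to the exact emitted values
        counts = matrix.counts.to_numpy(dtype=float)
        expected = [_noise_free_flags(matrix, counts[i], rules) for i in
                    range(len(gene_ids))]
        exp_ab = [e[0] for e in expected]
        exp_early = [e[1] for e in expected]
        exp_late = [e[2] for e in expected]
    else:
        # stochastic: truth is the intended construction, asserted in
        # aggregate (sensitivity/specificity), not per gene
        exp_ab = [mu_scaled[i].sum() >= rules.min_raw_total for i in
                  range(len(gene_ids))]
        exp_early = [m[3] and exp_ab[i] for i, m in enumerate(meta)]
        exp_late = [m[4] and exp_ab[i] for i, m in enumerate(meta)]

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": [m[1] for m in meta],
            "decoy_kind": [m[2] for m in meta],
            "expected_passes_abundance": exp_ab,
            "expected_early_up": exp_early,
            "expected_late_up": exp_late,
        }
    ).set_index("gene_id")

    pathways: dict[str, bool] = {}
    early_set = set(genes.index[genes["expected_early_up"]])
    for scenario in cfg.pathway_scenarios:
        fixture = load_packaged_pathway(scenario.pathway_id)
        pathways[scenario.pathway_id] = _expected_comprehensive(
            fixture, early_set
        )
    return SyntheticTruth(genes=genes, pathways=pathways)


def _noise_free_flags(
    matrix: CountMatrix, row: np.ndarray, rules: ClassifierConfig
) -> tuple[bool, bool, bool]:
    """Apply the filtering rules to one gene's exact (replicate-identical)
    values; SEM is zero so bar separation reduces to a strict mean inequality."""
    cols = list(matrix.counts.columns)

    def group_mean(cond: str, tp: str) -> float:
        s = matrix.samples_in_group(cond, tp)
        return float(np.mean([row[cols.index(x)] for x in s]))

    pc, thr = rules.pseudocount, rules.fold_threshold
    total = float(row.sum())
    abundant = total >= rules.min_raw_total
    ctl1, ctl7, ctl28 = (group_mean("CTL", t) for t in ("P1", "P7", "P28"))
    mi7, mi28 = group_mean("MI", "P7"), group_mean("MI", "P28")
    early = (
        abundant
        and (mi7 + pc) >= thr * (ctl7 + pc)
        and mi7 > ctl7
        and ctl7 <= ctl1
    )
    late = abundant and (mi28 + pc) >= thr * (ctl28 + pc)
    return abundant, early, late


def _expected_comprehensive(fixture: PathwayGraph, upregulated: set[str]) -> bool:
    """Topology-level expectation: does a chain of nodes with at least one
    upregulated member connect an initiator to an effector?"""
    satisfied = {
        nid
        for nid, node in fixture.nodes.items()
        if any(m in upregulated for m in node.members)
    }
    sub = fixture.to_networkx().subgraph(satisfied)
    for init in fixture.initiators():
        if init not in satisfied:
            continue
        for eff in fixture.effectors():
            if eff in satisfied and nx.has_path(sub, init, eff):
                return True
    return False


# ---------------------------------------------------------------------------
# config (de)serialization for the pipeline front end


def simconfig_from_dict(data: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (YAML/JSON pipeline configs)."""
    kwargs = dict(data)
    if "baseline_log_mean" in kwargs:
        kwargs["baseline_log_mean"] = tuple(kwargs["baseline_log_mean"])
    if kwargs.get("library_size_range") is not None:
        kwargs["library_size_range"] = tuple(kwargs["library_size_range"])
    kwargs["planted_early"] = tuple(
        PlantedGene(**p) for p in kwargs.get("planted_early", [])
    )
    kwargs["planted_decoys"] = tuple(
        Decoy(**d) for d in kwargs.get("planted_decoys", [])
    )
    kwargs["pathway_scenarios"] = tuple(
        PathwayScenario(**s) for s in kwargs.get("pathway_scenarios", [])
    )
    return SimConfig(**kwargs)


def simconfig_to_dict(cfg: SimConfig) -> dict:
    return {
        "n_genes": cfg.n_genes,
        "n_replicates": cfg.n_replicates,
        "baseline_log_mean": list(cfg.baseline_log_mean),
        "dispersion": cfg.dispersion,
        "planted_early": [
            {"gene_id": p.gene_id, "fold": p.fold, "persists": p.persists}
            for p in cfg.planted_early
        ],
        "planted_decoys": [
            {"gene_id": d.gene_id, "kind": d.kind} for d in cfg.planted_decoys
        ],
        "pathway_scenarios": [
            {
                "pathway_id": s.pathway_id,
                "satisfied": s.satisfied,
                "break_node": s.break_node,
            }
            for s in cfg.pathway_scenarios
        ],
        "seed": cfg.seed,
        "noise_free": cfg.noise_free,
        "library_size_range": list(cfg.library_size_range)
        if cfg.library_size_range
        else None,
    }
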