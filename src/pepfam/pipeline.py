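"""End-to-end orchestration of peptide-family and receptor discovery.

Two published procedures are wired together from the package modules:

* peptide route — expression screen, iterative profile search, similarity
  network + seed-community selection, six-frame genomic rescue, merge into
  the relaxed set, cysteine-spacing refinement into the confident set,
  then alignment, NJ phylogeny, rooting, age-cutoff clades and an
  occupancy-trimmed logo;
* receptor route — minimum-length filter, calibrated profile search,
  50%-identity network and seed communities, LRR + kinase filtering,
  signal-peptide removal, TM segmentation, ectodomain/kinase extraction
  and three phylogenies with age-cutoff clades.

Every run is deterministic under ``rng_seed`` and emits a manifest
echoing the fully resolved configuration plus per-stage candidate counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import align, famfilter, netcluster, phylo, profilesearch, screen, seqio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds of both discovery routes.

    Defaults are the peptide ('ctnip') preset; :meth:`preset` switches the
    network threshold, clade age cutoff and inclusion E-value to the
    receptor ('rk') literals.
    """

    screen_max_len: int = 150
    screen_require_sp: bool = True
    screen_top_n: int = 5
    peptide_max_len: int = 300
    peptide_min_len: int = 25
    rk_min_len: int = 500
    rk_min_lrr: int = 4
    network_threshold_pct: float = 20.0
    network_min_score: float = netcluster.EDGE_MIN_SCORE
    cys_min_gap: int = 9
    cys_max_gap: int = 11
    clade_age_cutoff: float = 9.0
    logo_occupancy_min: float = 0.05
    search_inclusion_evalue: float = 1e-5
    search_rounds: int = 5
    search_min_pct: float = 20.0
    search_min_score: float = 50.0
    bootstrap_n: int = 1000
    rng_seed: int = 0
    manual_exclusions: list[str] = field(default_factory=list)
    expression_column: str = "flg22_90min"

    def __post_init__(self) -> None:
        if self.cys_min_gap > self.cys_max_gap:
            raise ValueError("cys_min_gap > cys_max_gap")
        for name in ("screen_max_len", "peptide_max_len", "rk_min_len",
                     "search_rounds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.logo_occupancy_min <= 1:
            raise ValueError("logo_occupancy_min must be in [0, 1]")

    @classmethod
    def preset(cls, name: str, **overrides) -> "PipelineConfig":
        if name == "ctnip":
            base = dict()
        elif name == "rk":
            base = dict(network_threshold_pct=50.0, clade_age_cutoff=5.5,
                        search_inclusion_evalue=1e-10)
        else:
            raise ValueError(f"unknown preset {name!r}")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a flat mapping of dotted keys (e.g. ``screen.max_len``)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        remap = {
            "screen.max_len": "screen_max_len",
            "screen.require_sp": "screen_require_sp",
            "peptide.max_len": "peptide_max_len",
            "rk.min_len": "rk_min_len",
            "network.threshold_pct": "network_threshold_pct",
            "cys.min_gap": "cys_min_gap",
            "cys.max_gap": "cys_max_gap",
            "clade.age_cutoff": "clade_age_cutoff",
            "logo.occupancy_min": "logo_occupancy_min",
            "search.inclusion_E": "search_inclusion_evalue",
            "search.rounds": "search_rounds",
            "bootstrap.n": "bootstrap_n",
        }
        kwargs = {}
        for key, value in raw.items():
            attr = remap.get(key, key.replace(".", "_"))
            if not hasattr(cls, "__dataclass_fields__") or attr not in cls.__dataclass_fields__:
                raise KeyError(f"unknown config key {key!r}")
            kwargs[attr] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EvaluationReport:
    """Recall/precision of a discovered set against planted truth."""

    stage: str
    n_candidates: int
    n_truth: int
    recall: float
    precision: float
    false_positives: list[str]
    false_negatives: list[str]
    unannotated_fraction: float


@dataclass
class PeptideDiscoveryResult:
    screen_table: pd.DataFrame
    seeds: list[seqio.SequenceRecord]
    protein_candidates: famfilter.CandidateSet
    dna_hits: pd.DataFrame
    relaxed: famfilter.CandidateSet
    confident: famfilter.CandidateSet
    msa: seqio.Msa
    tree: seqio.PhyloTree
    clades: phylo.CladeSet
    logo: phylo.LogoMatrix
    partition: netcluster.Partition
    manifest: dict


@dataclass
class RkDiscoveryResult:
    retained: list[seqio.SequenceRecord]
    segmentations: dict[str, famfilter.DomainSegmentation]
    ectodomains: list[seqio.SequenceRecord]
    kinase_domains: list[seqio.SequenceRecord]
    trees: dict[str, seqio.PhyloTree]
    clades: phylo.CladeSet
    manifest: dict


def run_peptide_discovery(proteome: Sequence[seqio.SequenceRecord],
                          expression: pd.DataFrame,
                          genomes: Sequence[seqio.SequenceRecord] = (),
                          annotations: Sequence[seqio.IntervalAnnotation] = (),
                          seeds: Sequence[seqio.SequenceRecord] | None = None,
                          config: PipelineConfig | None = None,
                          out_dir=None) -> PeptideDiscoveryResult:
    """Full peptide-family discovery run.

    With ``seeds=None`` the top-ranked screen candidates become the seed
    set, reproducing a de-novo discovery; explicit seeds reproduce a
    knowledge-driven search.  An empty ``genomes`` sequence skips the DNA
    rescue stage (protein-only ablation).
    """
    cfg = config or PipelineConfig()
    counts: dict[str, int] = {}

    db = famfilter.length_filter(proteome, cfg.peptide_min_len,
                                 cfg.peptide_max_len)
    counts["proteome"] = len(proteome)
    counts["length_filtered"] = len(db)

    screen_table = screen.screen_short_secreted(
        db, expression, max_len=cfg.screen_max_len,
        column=cfg.expression_column, require_sp=cfg.screen_require_sp,
    )
    counts["screen"] = len(screen_table)
    by_id = {r.id: r for r in db}
    if seeds is None:
        top = screen_table.dropna(subset=["log2fc"]).head(cfg.screen_top_n)
        seeds = [by_id[i] for i in top["id"]]
        logger.info("screen-derived seeds: %s", [s.id for s in seeds])
    seeds = list(seeds)
    if not seeds:
        raise ValueError("no seed sequences (screen empty and none provided)")

    hits, profile, included = profilesearch.iterative_search(
        seeds, db, rounds=cfg.search_rounds,
        inclusion_evalue=cfg.search_inclusion_evalue,
        min_pct=cfg.search_min_pct, min_score=cfg.search_min_score,
        rng_seed=cfg.rng_seed,
    )
    counts["search_included"] = len(included)

    graph = netcluster.build_similarity_graph(
        included, threshold_pct=cfg.network_threshold_pct,
        min_score=cfg.network_min_score,
    )
    partition = netcluster.louvain(graph, rng_seed=cfg.rng_seed)
    protein_candidates = netcluster.select_seed_communities(
        partition, [s.id for s in seeds], included,
    )
    counts["seed_communities"] = len(protein_candidates)

    if profile is None and len(protein_candidates.members) >= 2:
        cand_msa = align.progressive_msa(protein_candidates.members)
        profile = profilesearch.build_profile(cand_msa)
    if genomes and profile is not None:
        dna_hits, rescued = profilesearch.dna_rescue(
            list(genomes), list(annotations), profile,
            min_aa=cfg.peptide_min_len, max_aa=cfg.peptide_max_len,
            max_evalue=cfg.search_inclusion_evalue, rng_seed=cfg.rng_seed,
        )
    else:
        if not genomes:
            logger.info("no genomes supplied; skipping DNA rescue")
        dna_hits, rescued = pd.DataFrame(), []
    counts["dna_rescued"] = len(rescued)

    relaxed = profilesearch.merge_candidates(protein_candidates.members, rescued)
    counts["relaxed"] = len(relaxed)
    confident = famfilter.refine_confident(
        relaxed, cfg.manual_exclusions, cfg.cys_min_gap, cfg.cys_max_gap,
    )
    counts["confident"] = len(confident)

    msa = align.progressive_msa(relaxed.members)
    dm = phylo.msa_distance(msa, model="poisson")
    tree = phylo.nj_tree(dm) if len(relaxed) >= 3 else None
    rooted = phylo.root_tree(tree, midpoint=True) if tree is not None else None
    clades = phylo.clades_by_age(rooted, cfg.clade_age_cutoff) \
        if rooted is not None else phylo.CladeSet([], cfg.clade_age_cutoff)
    counts["clades"] = len(clades)

    confident_msa = align.progressive_msa(confident.members) \
        if len(confident) >= 2 else msa
    logo = phylo.sequence_logo(confident_msa, cfg.logo_occupancy_min)

    manifest = dict(config=cfg.to_dict(), stage_counts=counts,
                    seed_ids=[s.id for s in seeds])
    result = PeptideDiscoveryResult(
        screen_table=screen_table, seeds=seeds,
        protein_candidates=protein_candidates, dna_hits=dna_hits,
        relaxed=relaxed, confident=confident, msa=msa, tree=rooted,
        clades=clades, logo=logo, partition=partition, manifest=manifest,
    )
    if out_dir is not None:
        _write_peptide_outputs(result, Path(out_dir))
    return result


def run_rk_discovery(proteome: Sequence[seqio.SequenceRecord],
                     seeds: Sequence[seqio.SequenceRecord],
                     config: PipelineConfig | None = None,
                     outgroup: str | None = None,
                     out_dir=None) -> RkDiscoveryResult:
    """Receptor-kinase family delineation run."""
    cfg = config or PipelineConfig.preset("rk")
    counts: dict[str, int] = {}
    seeds = list(seeds)
    if not seeds:
        raise ValueError("receptor search needs seed sequences")

    db = famfilter.length_filter(proteome, cfg.rk_min_len, None)
    counts["length_filtered"] = len(db)

    if len(seeds) >= 2:
        seed_msa = align.progressive_msa(seeds)
        profile = profilesearch.build_profile(seed_msa)
        model = profilesearch.calibrate_evalue(profile, db,
                                               rng_seed=cfg.rng_seed)
        hits = profilesearch.profile_search(
            profile, db, model, max_evalue=cfg.search_inclusion_evalue,
        )
        by_id = {r.id: r for r in db}
        candidates = {s.id: s for s in seeds}
        for tid in hits["target"]:
            candidates.setdefault(tid, by_id[tid])
        candidates = list(candidates.values())
    else:
        table = align.all_vs_seed_search(db, seeds,
                                         min_pct=cfg.search_min_pct,
                                         min_score=cfg.search_min_score)
        by_id = {r.id: r for r in db}
        candidates = {s.id: s for s in seeds}
        for tid in table["subject"]:
            candidates.setdefault(tid, by_id[tid])
        candidates = list(candidates.values())
    counts["search"] = len(candidates)

    graph = netcluster.build_similarity_graph(
        candidates, threshold_pct=cfg.network_threshold_pct,
        min_score=cfg.network_min_score,
    )
    partition = netcluster.louvain(graph, rng_seed=cfg.rng_seed)
    selected = netcluster.select_seed_communities(
        partition, [s.id for s in seeds], candidates,
    )
    counts["seed_communities"] = len(selected)

    retained = famfilter.rk_filter(selected.members, min_len=cfg.rk_min_len,
                                   min_lrr=cfg.rk_min_lrr)
    counts["lrr_kinase"] = len(retained)

    segmentations, ectos, kinases = {}, [], []
    for rec in retained:
        seg = famfilter.tm_segments(rec)
        segmentations[rec.id] = seg
        ectos.append(famfilter.extract_ectodomain(rec, seg))
        kin = famfilter.detect_kinase_domain(rec)
        if kin is not None:
            kinases.append(rec.fragment(kin[0], kin[1]))

    trees: dict[str, seqio.PhyloTree] = {}
    for label, records in (("full", retained), ("ectodomain", ectos),
                           ("kinase", kinases)):
        if len(records) >= 3:
            msa = align.progressive_msa(records)
            tree = phylo.nj_tree(phylo.msa_distance(msa, model="poisson"))
            if outgroup is not None and label == "full":
                tree = phylo.root_tree(tree, outgroup=outgroup)
            else:
                tree = phylo.root_tree(tree, midpoint=True)
            trees[label] = tree
    clades = phylo.clades_by_age(trees["full"], cfg.clade_age_cutoff) \
        if "full" in trees else phylo.CladeSet([], cfg.clade_age_cutoff)
    counts["clades"] = len(clades)

    manifest = dict(config=cfg.to_dict(), stage_counts=counts,
                    seed_ids=[s.id for s in seeds])
    result = RkDiscoveryResult(
        retained=retained, segmentations=segmentations, ectodomains=ectos,
        kinase_domains=kinases, trees=trees, clades=clades, manifest=manifest,
    )
    if out_dir is not None:
        _write_rk_outputs(result, Path(out_dir))
    return result


def evaluate(candidates: famfilter.CandidateSet,
             truth: pd.DataFrame,
             reference_records: Sequence[seqio.SequenceRecord],
             stage: str | None = None) -> EvaluationReport:
    """Recall/precision of a candidate set against a planted truth table.

    De-novo candidates carry coordinate-derived ids, so matching is by
    (species, sequence) against the reference records named in the truth
    table; seed records are ignored.
    """
    ref_by_id = {r.id: r for r in reference_records}
    missing = set(truth["id"]) - set(ref_by_id)
    if missing:
        raise ValueError(f"truth ids missing from reference records: {sorted(missing)[:5]}")
    truth_fam = truth[truth["is_family"]] if "is_family" in truth.columns else truth
    seq_to_truth = {
        (ref_by_id[t.id].species, ref_by_id[t.id].residues): t.id
        for t in truth_fam.itertuples()
    }
    annotated = dict(zip(truth_fam["id"], truth_fam.get("annotated", True)))

    found: set[str] = set()
    false_pos: list[str] = []
    for rec in candidates.members:
        if rec.source == "seed":
            continue
        tid = seq_to_truth.get((rec.species, rec.residues))
        if tid is None and rec.id in annotated:
            tid = rec.id
        if tid is not None:
            found.add(tid)
        else:
            false_pos.append(rec.id)
    false_neg = sorted(set(truth_fam["id"]) - found)
    n_pred = len(found) + len(false_pos)
    recall = len(found) / len(truth_fam) if len(truth_fam) else 1.0
    precision = len(found) / n_pred if n_pred else 1.0
    unann = sum(1 for t in found if not annotated.get(t, True))
    return EvaluationReport(
        stage=stage or candidates.stage, n_candidates=n_pred,
        n_truth=len(truth_fam), recall=recall, precision=precision,
        false_positives=sorted(false_pos), false_negatives=false_neg,
        unannotated_fraction=unann / len(found) if found else 0.0,
    )


# ---------------------------------------------------------------------------
# Output writers


def _write_peptide_outputs(result: PeptideDiscoveryResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.screen_table.to_csv(out_dir / "screen.tsv", sep="\t", index=False)
    if result.relaxed.members:
        seqio.write_fasta(result.relaxed.members, out_dir / "relaxed.fasta")
    if result.confident.members:
        seqio.write_fasta(result.confident.members, out_dir / "confident.fasta")
    seqio.write_msa_fasta(result.msa, out_dir / "relaxed.align.fasta")
    if result.tree is not None:
        seqio.write_newick(result.tree, out_dir / "tree.nwk")
    _write_clades(result.clades, out_dir / "clades.tsv")
    _write_logo(result.logo, out_dir / "logo.tsv")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def _write_rk_outputs(result: RkDiscoveryResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.retained:
        seqio.write_fasta(result.retained, out_dir / "receptors.fasta")
    if result.ectodomains:
        seqio.write_fasta(result.ectodomains, out_dir / "ectodomains.fasta")
    if result.kinase_domains:
        seqio.write_fasta(result.kinase_domains, out_dir / "kinase_domains.fasta")
    for label, tree in result.trees.items():
        seqio.write_newick(tree, out_dir / f"tree_{label}.nwk")
    _write_clades(result.clades, out_dir / "clades.tsv")
    segments = [
        seqio.IntervalAnnotation(seq_id=sid, start=s.start, end=s.end,
                                 strand="+", feature=s.label)
        for sid, seg in result.segmentations.items() for s in seg.segments
    ]
    if segments:
        seqio.write_intervals(segments, out_dir / "segments.tsv")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def _write_clades(clades: phylo.CladeSet, path: Path) -> None:
    lines = [f"{cid}\t{age:.6g}\t{','.join(leaves)}"
             for cid, leaves, age in clades.clades]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _write_logo(logo: phylo.LogoMatrix, path: Path) -> None:
    header = "column\t" + "\t".join(phylo._AA20) + "\tIC"
    lines = [header]
    for k, col in enumerate(logo.columns):
        freqs = "\t".join(f"{v:.6g}" for v in logo.frequencies[k])
        lines.append(f"{col}\t{freqs}\t{logo.information[k]:.6g}")
    path.write_text("\n".join(lines) + "\n")
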