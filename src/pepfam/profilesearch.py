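"""Position-profile construction, calibrated search, and genomic rescue.

A position-specific scoring model (log-odds over the 20 residues with
pseudocounts) is built from a multiple alignment, calibrated against
residue-shuffled null targets with a Gumbel extreme-value fit, and used
for three jobs:

* iterative proteome search that grows the candidate set to a fixpoint,
* scoring of six-frame ORFs from genomes to rescue unannotated members
  (annotated regions are masked out), and
* merging protein-route and DNA-route candidates into the relaxed set.

The model is a PSSM with affine gap penalties, not a full profile HMM
with learned transition probabilities; at the scale this package targets
the two behave equivalently for family recruitment, and the PSSM keeps
every score and E-value exactly reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align import (DEFAULT_SCHEME, ScoringScheme, _fill_local, all_vs_seed_search,
                    encode, progressive_msa, ALPHABET)
from .famfilter import CandidateSet
from .seqio import IntervalAnnotation, Msa, SequenceRecord, reverse_complement, translate

logger = logging.getLogger(__name__)

#: affine gap penalties for profile-sequence alignment, in bits
PROFILE_GAP_OPEN = -4.0
PROFILE_GAP_EXTEND = -0.5
#: minimum fraction of non-gap residues for a column to become a match column
MATCH_COLUMN_OCCUPANCY = 0.5

_EULER_GAMMA = 0.5772156649015329


@dataclass
class PositionProfile:
    """Per-column log2-odds scoring model built from an alignment.

    ``log_odds`` is (L x 21): 20 residue scores per match column plus a
    zero X column (ambiguous residues score as background).  ``probs``
    stores the underlying per-column residue probabilities (sum to 1).
    """

    log_odds: np.ndarray
    probs: np.ndarray
    consensus: str
    background: np.ndarray
    alpha: float
    source_columns: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]


@dataclass
class EvalueModel:
    """Gumbel tail fitted to null (shuffled-target) scores.

    ``E(s) = N * P(S >= s)`` with ``P`` from the fitted extreme-value
    distribution; E is monotone decreasing in s and exactly proportional
    to the database size N.
    """

    mu: float
    lam: float
    n_database: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("Gumbel scale lambda must be positive")

    def pvalue(self, score: float) -> float:
        x = math.exp(-self.lam * (score - self.mu))
        return float(-np.expm1(-x))

    def evalue(self, score: float, n_database: int | None = None) -> float:
        n = self.n_database if n_database is None else n_database
        return n * self.pvalue(score)


def build_profile(msa: Msa, alpha: float = 1.0,
                  background: np.ndarray | None = None) -> PositionProfile:
    """Pseudocount log-odds profile from an alignment.

    Columns with non-gap occupancy below 50% are dropped (match-column
    rule); per column, ``p_c = (count_c + alpha * b_c) / (n + alpha)``
    with ``n`` the ungapped count.  X residues count toward occupancy but
    not toward any residue.
    """
    if msa.n_rows == 0:
        raise ValueError("empty alignment")
    if alpha <= 0:
        raise ValueError("pseudocount weight alpha must be > 0")
    if background is None:
        background = np.full(20, 0.05)
    background = np.asarray(background, dtype=float)
    n_rows = msa.n_rows
    cols, probs_rows, lo_rows, consensus = [], [], [], []
    for j in range(msa.n_cols):
        col = msa.column(j)
        nongap = [c for c in col if c != "-"]
        if len(nongap) / n_rows < MATCH_COLUMN_OCCUPANCY:
            continue
        counts = np.zeros(20)
        n_eff = 0
        for c in nongap:
            k = ALPHABET.find(c)
            if 0 <= k < 20:
                counts[k] += 1
                n_eff += 1
        if n_eff == 0:
            continue
        p = (counts + alpha * background) / (n_eff + alpha)
        probs_rows.append(p)
        lo_rows.append(np.log2(p / background))
        consensus.append(ALPHABET[int(np.argmax(p))])
        cols.append(j)
    if not cols:
        raise ValueError("all columns dropped (all-gap or low occupancy)")
    probs = np.vstack(probs_rows)
    log_odds = np.column_stack([np.vstack(lo_rows), np.zeros(len(cols))])
    return PositionProfile(
        log_odds=log_odds, probs=probs, consensus="".join(consensus),
        background=background, alpha=alpha, source_columns=cols,
    )


def score_profile_target(profile: PositionProfile, residues: str) -> tuple[float, int, int]:
    """Best local profile-vs-sequence alignment score (bits).

    Affine gaps model profile-column deletion and target insertion.
    Returns (score, t_start, t_end) with a 1-based inclusive target range;
    (0, 0, 0) when nothing scores positively.
    """
    if not residues:
        return 0.0, 0, 0
    M = np.ascontiguousarray(profile.log_odds[:, encode(residues)])
    H, E, F, best, bi, bj = _fill_local(M, PROFILE_GAP_OPEN, PROFILE_GAP_EXTEND)
    if best <= 0:
        return 0.0, 0, 0
    from .align import traceback_local
    _, _, j0 = traceback_local(H, E, F, M, PROFILE_GAP_OPEN,
                               PROFILE_GAP_EXTEND, bi, bj)
    return float(best), j0 + 1, bj


def calibrate_evalue(profile: PositionProfile, db: Sequence[SequenceRecord],
                     n_shuffles: int = 200, rng_seed: int = 0) -> EvalueModel:
    """Fit a Gumbel null by scoring residue-shuffled database targets.

    Method-of-moments fit: ``lambda = pi / (sigma * sqrt(6))``,
    ``mu = mean - gamma / lambda`` (Euler–Mascheroni gamma).  Deterministic
    under the seed; a degenerate null (zero variance) is an error.
    """
    if n_shuffles < 100:
        raise ValueError("need >= 100 shuffles for a stable tail fit")
    if not db:
        raise ValueError("empty calibration database")
    rng = np.random.default_rng(rng_seed)
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        target = db[k % len(db)]
        chars = np.array(list(target.residues))
        rng.shuffle(chars)
        scores[k], _, _ = score_profile_target(profile, "".join(chars))
    sigma = float(np.std(scores))
    if sigma == 0.0:
        raise ValueError("degenerate null score distribution (sigma = 0)")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = float(np.mean(scores)) - _EULER_GAMMA / lam
    return EvalueModel(mu=mu, lam=lam, n_database=len(db))


def profile_search(profile: PositionProfile, db: Sequence[SequenceRecord],
                   model: EvalueModel | None = None,
                   max_evalue: float = 10.0,
                   calibration_seed: int | None = 0,
                   n_shuffles: int = 200) -> pd.DataFrame:
    """Score every database record against the profile; report by E-value.

    With no model supplied the null is calibrated on the fly from the
    database itself (requires ``calibration_seed``); hits with
    E <= ``max_evalue`` are returned sorted by ascending E.
    """
    if model is None:
        if calibration_seed is None:
            raise ValueError("no E-value model and on-the-fly calibration disabled")
        model = calibrate_evalue(profile, db, n_shuffles=n_shuffles,
                                 rng_seed=calibration_seed)
    rows = []
    for rec in db:
        score, t_start, t_end = score_profile_target(profile, rec.residues)
        ev = model.evalue(score, n_database=len(db))
        if ev <= max_evalue:
            rows.append(dict(
                target=rec.id, species=rec.species, t_start=t_start,
                t_end=t_end, strand=".", score=score, evalue=ev,
                provenance="protein-search",
            ))
    table = pd.DataFrame(
        rows, columns=["target", "species", "t_start", "t_end", "strand",
                       "score", "evalue", "provenance"],
    )
    return table.sort_values(["evalue", "target"]).reset_index(drop=True)


def iterative_search(seeds: Sequence[SequenceRecord],
                     db: Sequence[SequenceRecord],
                     scheme: ScoringScheme = DEFAULT_SCHEME,
                     rounds: int = 5,
                     inclusion_evalue: float = 1e-5,
                     min_pct: float = 20.0,
                     min_score: float = 50.0,
                     alpha: float = 1.0,
                     rng_seed: int = 0) -> tuple[pd.DataFrame, PositionProfile | None, list[SequenceRecord]]:
    """Iterative family recruitment to a fixpoint.

    Round 1 recruits by pairwise seed search; each later round realigns
    the included set, rebuilds and recalibrates the profile, re-searches
    the database and adds targets at E <= ``inclusion_evalue``.  Stops
    when a round adds nothing or after ``rounds`` rounds.  The included
    set grows monotonically.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    by_id = {rec.id: rec for rec in db}
    hits = all_vs_seed_search(db, seeds, scheme, min_pct=min_pct,
                              min_score=min_score)
    included: dict[str, SequenceRecord] = {s.id: s for s in seeds}
    for tid in hits["subject"]:
        included.setdefault(tid, by_id[tid])
    last_table = pd.DataFrame(
        dict(target=hits["subject"], species=hits["species"],
             t_start=hits["s_start"], t_end=hits["s_end"], strand=".",
             score=hits["score"], evalue=np.nan, provenance="protein-search")
    )
    profile = None
    for rnd in range(2, rounds + 1):
        if len(included) < 2:
            break
        msa = progressive_msa(list(included.values()), scheme)
        profile = build_profile(msa, alpha=alpha)
        model = calibrate_evalue(profile, db, rng_seed=rng_seed + rnd)
        table = profile_search(profile, db, model, max_evalue=inclusion_evalue)
        new = [t for t in table["target"] if t not in included]
        last_table = table
        logger.info("iteration %d: %d hits, %d new", rnd, len(table), len(new))
        if not new:
            break
        for tid in new:
            included[tid] = by_id[tid]
    return last_table, profile, list(included.values())


# ---------------------------------------------------------------------------
# Six-frame genomic rescue


def find_orfs(genome: SequenceRecord, min_aa: int = 25, max_aa: int = 400):
    """Six-frame ORFs (first ATG after a stop, through the stop codon).

    Yields (protein, start, end, strand, frame) with a 1-based inclusive
    genomic interval covering ATG..stop on the plus-strand coordinate
    system regardless of strand.
    """
    L = len(genome.residues)
    for strand, seq in (("+", genome.residues),
                        ("-", reverse_complement(genome.residues))):
        for frame in range(3):
            aa = translate(seq[frame:])
            start_idx = None
            for i, c in enumerate(aa):
                if c == "M" and start_idx is None:
                    start_idx = i
                elif c == "*":
                    if start_idx is not None:
                        plen = i - start_idx
                        if min_aa <= plen <= max_aa:
                            nt_start = frame + 3 * start_idx + 1
                            nt_end = frame + 3 * i + 3
                            if strand == "-":
                                nt_start, nt_end = L - nt_end + 1, L - nt_start + 1
                            yield (aa[start_idx:i], min(nt_start, nt_end),
                                   max(nt_start, nt_end), strand, frame)
                    start_idx = None


def dna_rescue(genomes: Sequence[SequenceRecord],
               annotations: Sequence[IntervalAnnotation],
               profile: PositionProfile,
               min_aa: int = 25, max_aa: int = 400,
               max_evalue: float = 1e-5,
               rng_seed: int = 0) -> tuple[pd.DataFrame, list[SequenceRecord]]:
    """Rescue unannotated family members from genomic DNA.

    Six-frame ORFs within the length bounds are scored against the
    profile (E-values calibrated on the shuffled ORF set); ORFs whose
    genomic interval overlaps any annotated feature by >= 1 bp are
    discarded, and survivors are emitted as de-novo protein records.
    """
    if not annotations:
        logger.warning("no annotation table supplied; treating as empty")
    orfs: list[tuple[SequenceRecord, int, int, str, int, str]] = []
    for genome in genomes:
        for protein, start, end, strand, frame in find_orfs(genome, min_aa, max_aa):
            rec = SequenceRecord(
                id=f"{genome.id}:{start}-{end}({strand})", residues=protein,
                species=genome.species, moltype="protein", source="denovo",
            )
            orfs.append((rec, start, end, strand, frame, genome.id))
    if not orfs:
        return pd.DataFrame(columns=["target", "species", "t_start", "t_end",
                                     "strand", "score", "evalue",
                                     "provenance"]), []
    orf_records = [o[0] for o in orfs]
    model = calibrate_evalue(profile, orf_records, rng_seed=rng_seed)
    by_genome: dict[str, list[IntervalAnnotation]] = {}
    for ann in annotations:
        by_genome.setdefault(ann.seq_id, []).append(ann)
    rows, rescued = [], []
    for rec, start, end, strand, frame, genome_id in orfs:
        if any(a.overlaps(start, end) for a in by_genome.get(genome_id, [])):
            continue
        score, _, _ = score_profile_target(profile, rec.residues)
        ev = model.evalue(score, n_database=len(orf_records))
        if ev <= max_evalue:
            rows.append(dict(
                target=rec.id, species=rec.species, t_start=start, t_end=end,
                strand=strand, score=score, evalue=ev, provenance="dna-search",
            ))
            rescued.append(rec)
    table = pd.DataFrame(
        rows, columns=["target", "species", "t_start", "t_end", "strand",
                       "score", "evalue", "provenance"],
    ).sort_values(["evalue", "target"]).reset_index(drop=True)
    return table, rescued


def merge_candidates(protein_candidates: Sequence[SequenceRecord],
                     dna_candidates: Sequence[SequenceRecord]) -> CandidateSet:
    """Union of both search routes, deduplicated by (species, sequence).

    When the same sequence arrives from both routes the annotated-route
    entry wins, so provenance reflects the stronger evidence.
    """
    chosen: dict[tuple[str, str], SequenceRecord] = {}
    for rec in list(protein_candidates) + list(dna_candidates):
        key = (rec.species, rec.residues)
        if key in chosen:
            if chosen[key].source != "annotated" and rec.source == "annotated":
                chosen[key] = rec
        else:
            chosen[key] = rec
    members = list(chosen.values())
    return CandidateSet(
        stage="relaxed", members=members,
        provenance={m.id: m.source for m in members},
    )
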