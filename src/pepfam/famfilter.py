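"""Family-membership filters and receptor domain segmentation.

Two families of rules live here:

* peptide side — length bounds, the relaxed→confident cysteine-spacing
  filter (two cysteines separated by 9–11 intervening residues), and a
  rule-based signal-peptide caller;
* receptor side — Kyte–Doolittle transmembrane segmentation, ectodomain
  extraction (longest extracellular stretch), kinase-domain motif triad
  detection and leucine-rich-repeat (LRR) counting.

The SP/TM/kinase/LRR callers are transparent heuristics standing in for
SignalP, TMHMM and PFAM profile scans: their thresholds are package
constants, and no fidelity to the real predictors' probabilities is
claimed.  The synthetic benchmark generator is co-designed so that recall
on planted truth under these rules is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

SMALL_RESIDUES = frozenset("AGSCTV")   # SignalP-like -3/-1 cleavage rule
BASIC_RESIDUES = frozenset("KR")
HYDROPHOBIC_CORE_MIN = 1.8             # mean KD over the SP h-region window
TM_WINDOW = 19
TM_THRESHOLD = 1.6                     # mean KD calling a TM core window
SP_SEARCH_LIMIT = 30

# kinase motif geometry (ordered triad-plus: G-loop, VAIK lysine, HRD, DFG)
KINASE_K_WITHIN = 30
KINASE_DFG_WITHIN = 60

LRR_CONSENSUS = "LXXLXLXXNXL"          # positions 1,4,6,11 aliphatic; 9 is N
_LRR_ALIPHATIC = frozenset("LIVF")


@dataclass
class CandidateSet:
    """A staged family hypothesis (relaxed or confident members).

    ``provenance`` maps member id -> how it entered the set; ``excluded``
    records ids removed by the explicit manual-exclusion list.
    """

    stage: str
    members: list[SequenceRecord] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in ("relaxed", "confident"):
            raise ValueError(f"unknown stage {self.stage!r}")

    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Segment:
    """A labelled 1-based inclusive protein segment."""

    label: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainSegmentation:
    """Ordered, non-overlapping domain segments of one protein."""

    seq_id: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end:
                raise ValueError(f"overlapping segments in {self.seq_id}")
            prev_end = seg.end

    def of_label(self, label: str) -> list[Segment]:
        return [s for s in self.segments if s.label == label]


# ---------------------------------------------------------------------------
# Peptide-side filters


def length_filter(records: Sequence[SequenceRecord],
                  min_len: int = 0,
                  max_len: int | None = None) -> list[SequenceRecord]:
    """Keep records with min_len <= length <= max_len (inclusive bounds)."""
    if max_len is not None and min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [
        r for r in records
        if len(r) >= min_len and (max_len is None or len(r) <= max_len)
    ]


def cysteine_spacing_filter(record: SequenceRecord, min_gap: int = 9,
                            max_gap: int = 11) -> bool:
    """True iff two cysteines are separated by min_gap..max_gap residues.

    The gap counts residues strictly between the two cysteines; the
    intervening residues may themselves contain no cysteine for the pair
    to count (a closer cysteine starts a new candidate pair).
    """
    seq = record.residues
    positions = [i for i, c in enumerate(seq) if c == "C"]
    for a, b in zip(positions, positions[1:]):
        if min_gap <= b - a - 1 <= max_gap:
            return True
    return False


def refine_confident(relaxed: CandidateSet,
                     exclusions: Iterable[str] = (),
                     min_gap: int = 9, max_gap: int = 11) -> CandidateSet:
    """Apply the cysteine-spacing filter and an explicit exclusion list.

    Mirrors the published relaxed→confident step in which a motif filter
    plus a documented manual removal list defines the confident set.
    Unknown exclusion ids are warned about and ignored.
    """
    if relaxed.stage != "relaxed":
        raise ValueError("refine_confident expects a relaxed set")
    exclusions = list(exclusions)
    known = set(relaxed.ids())
    for ex in exclusions:
        if ex not in known:
            logger.warning("exclusion id %r not in relaxed set; ignored", ex)
    excl = {e for e in exclusions if e in known}
    members = [
        m for m in relaxed.members
        if m.id not in excl and cysteine_spacing_filter(m, min_gap, max_gap)
    ]
    return CandidateSet(
        stage="confident",
        members=members,
        provenance={m.id: relaxed.provenance.get(m.id, m.source) for m in members},
        excluded=sorted(excl),
    )


def _mean_kd(seq: str) -> float:
    return sum(KYTE_DOOLITTLE.get(c, 0.0) for c in seq) / len(seq)


def predict_signal_peptide(record: SequenceRecord,
                           window: int = 8) -> Optional[tuple[int, int, float]]:
    """Rule-based signal-peptide call.

    Within the first 30 residues, require at least one K/R in the first 5
    residues and an 8-residue window of mean Kyte–Doolittle hydropathy
    >= 1.8 (the h-region).  The cleavage site is the first position after
    the hydrophobic core whose -3 and -1 residues are small (A,G,S,C,T,V).
    Returns (start, end, score) of the SP — always start=1 — or None.
    The score is the peak window hydropathy.
    """
    seq = record.residues
    if len(seq) < 25:
        return None
    head = seq[:SP_SEARCH_LIMIT]
    if not any(c in BASIC_RESIDUES for c in head[:5]):
        return None
    core_start = None
    best = -10.0
    for i in range(0, len(head) - window + 1):
        kd = _mean_kd(head[i : i + window])
        if kd > best:
            best = kd
        if kd >= HYDROPHOBIC_CORE_MIN and core_start is None:
            core_start = i  # 0-based
    if core_start is None:
        return None
    # extend the core while single-residue hydropathy stays high
    core_end = core_start + window - 1
    while core_end + 1 < len(head) and KYTE_DOOLITTLE.get(head[core_end + 1], 0.0) >= HYDROPHOBIC_CORE_MIN:
        core_end += 1
    # cleavage: first mature position p (1-based) after the core with
    # small residues at p-3 and p-1
    for p in range(core_end + 2, min(len(seq), SP_SEARCH_LIMIT + 6) + 1):
        if p - 3 >= 1 and seq[p - 4] in SMALL_RESIDUES and seq[p - 2] in SMALL_RESIDUES:
            if p - 1 <= core_end + 1:
                continue
            return (1, p - 1, best)
    return None


def remove_signal_peptide(record: SequenceRecord) -> SequenceRecord:
    """Return the mature protein (SP removed) or the record unchanged."""
    sp = predict_signal_peptide(record)
    if sp is None:
        return record
    return replace(record, residues=record.residues[sp[1]:])


# ---------------------------------------------------------------------------
# Receptor-side segmentation


def tm_segments(record: SequenceRecord) -> DomainSegmentation:
    """Sliding-window Kyte–Doolittle transmembrane segmentation.

    Windows of 19 residues with mean hydropathy >= 1.6 mark TM cores;
    overlapping calls merge.  Non-TM spans alternate extracellular /
    intracellular assuming type-I topology: the N-terminal side (after any
    signal peptide) is extracellular.
    """
    seq = record.residues
    sp = predict_signal_peptide(record)
    sp_end = sp[1] if sp else 0
    body = seq[sp_end:]
    n = len(body)
    tm_mask = [False] * n
    for i in range(0, n - TM_WINDOW + 1):
        if _mean_kd(body[i : i + TM_WINDOW]) >= TM_THRESHOLD:
            for k in range(i, i + TM_WINDOW):
                tm_mask[k] = True
    # trim hydrophilic residues smeared in by the window ends
    i = 0
    while i < n:
        if tm_mask[i]:
            j = i
            while j < n and tm_mask[j]:
                j += 1
            while i < j and KYTE_DOOLITTLE.get(body[i], 0.0) < TM_THRESHOLD:
                tm_mask[i] = False
                i += 1
            while j > i and KYTE_DOOLITTLE.get(body[j - 1], 0.0) < TM_THRESHOLD:
                tm_mask[j - 1] = False
                j -= 1
            i = j
        i += 1
    segments: list[Segment] = []
    if sp_end:
        segments.append(Segment("signal-peptide", 1, sp_end))
    i = 0
    side = "extracellular"  # type-I: N-terminus outside after the SP
    while i < n:
        j = i
        while j < n and tm_mask[j] == tm_mask[i]:
            j += 1
        if tm_mask[i]:
            label = "transmembrane"
        else:
            label = side
            side = "intracellular" if side == "extracellular" else "extracellular"
        if tm_mask[i]:
            pass
        segments.append(Segment(label, sp_end + i + 1, sp_end + j))
        i = j
    # alternation must only flip across a TM segment: rebuild labels
    rebuilt: list[Segment] = [s for s in segments if s.label == "signal-peptide"]
    side = "extracellular"
    for seg in segments:
        if seg.label == "signal-peptide":
            continue
        if seg.label == "transmembrane":
            rebuilt.append(seg)
            side = "intracellular" if side == "extracellular" else "extracellular"
        else:
            rebuilt.append(Segment(side, seg.start, seg.end))
    return DomainSegmentation(record.id, rebuilt)


def extract_ectodomain(record: SequenceRecord,
                       segmentation: DomainSegmentation | None = None) -> SequenceRecord:
    """Longest extracellular segment (ties broken N-terminal-most)."""
    if segmentation is None:
        segmentation = tm_segments(record)
    ecto = segmentation.of_label("extracellular")
    if not ecto:
        raise ValueError(f"no extracellular segment in {record.id}")
    best = max(ecto, key=lambda s: (len(s), -s.start))
    return record.fragment(best.start, best.end)


def detect_kinase_domain(record: SequenceRecord) -> Optional[tuple[int, int, int]]:
    """Ordered kinase motif scan: GxGxxG, K, HRD, DFG.

    Looks for the glycine-rich loop, a lysine within 30 residues of it,
    then HRD, then DFG within 60 residues of HRD.  Returns the minimal
    spanning 1-based range plus a motif count (0-4); a positive call needs
    >= 3 ordered motifs.  Returns None on a negative call.
    """
    seq = record.residues
    n = len(seq)
    # glycine-rich loop
    g_pos = None
    for i in range(n - 5):
        if seq[i] == "G" and seq[i + 2] == "G" and seq[i + 5] == "G":
            g_pos = i
            break
    motifs = 0
    start = None
    cursor = 0
    if g_pos is not None:
        motifs += 1
        start = g_pos
        cursor = g_pos + 6
        k_pos = seq.find("K", cursor, cursor + KINASE_K_WITHIN)
        if k_pos != -1:
            motifs += 1
            cursor = k_pos + 1
    hrd = seq.find("HRD", cursor)
    if hrd != -1:
        motifs += 1
        if start is None:
            start = hrd
        dfg = seq.find("DFG", hrd + 3, hrd + 3 + KINASE_DFG_WITHIN)
        if dfg != -1:
            motifs += 1
            end = dfg + 3
        else:
            end = hrd + 3
    else:
        end = cursor
    if motifs < 3 or start is None:
        return None
    return (start + 1, end, motifs)


def detect_lrr(record: SequenceRecord) -> tuple[int, list[tuple[int, int]]]:
    """Count leucine-rich repeats by consensus window matching.

    Slides the 11-residue LxxLxLxxNxL consensus; the four aliphatic
    positions (L/I/V/F accepted) plus the asparagine are the conserved
    positions, and a window is called at >= 5/6 matches.  Overlapping
    calls are resolved greedily left-to-right (non-overlapping selection).
    Returns (count, list of 1-based ranges).
    """
    seq = record.residues
    w = len(LRR_CONSENSUS)
    calls = []
    i = 0
    while i <= len(seq) - w:
        win = seq[i : i + w]
        # conserved positions: aliphatic at consensus L slots, plus the N
        score = sum(
            1 for k in (0, 3, 5, 10) if win[k] in _LRR_ALIPHATIC
        ) + (1 if win[8] == "N" else 0)
        if score >= 5:
            calls.append((i + 1, i + w))
            i += w  # greedy non-overlapping
        else:
            i += 1
    return len(calls), calls


def rk_filter(records: Sequence[SequenceRecord], min_len: int = 500,
              min_lrr: int = 4) -> list[SequenceRecord]:
    """Receptor-kinase candidate filter: length, LRR count, kinase triad."""
    kept = []
    for rec in records:
        if len(rec) < min_len:
            continue
        if detect_lrr(rec)[0] < min_lrr:
            continue
        if detect_kinase_domain(rec) is None:
            continue
        kept.append(rec)
    return kept


def extract_fragment(precursor: SequenceRecord, start: int, end: int) -> SequenceRecord:
    """Residues start..end (1-based inclusive) as a peptide record."""
    return precursor.fragment(start, end)
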