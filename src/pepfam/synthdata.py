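"""Deterministic synthetic multi-species benchmark generator.

Emulates the statistical structure the discovery pipeline assumes: a
planted secreted-peptide family with a conserved C-x(9–11)-C motif shared
across several species, a fraction of members present only in genomic DNA
(unannotated), short decoy proteins, elicitor-induced expression of family
transcripts, and a planted LRR receptor-kinase family.  Ground-truth
tables accompany every output so recall/precision of each pipeline stage
is measurable without any external download.

Design notes
------------
* Star phylogeny: every member is an independently mutated copy of one
  ancestor (no indels by default, so mature-region coordinates stay
  aligned across members).
* The signal-peptide region is built to satisfy the package's own SP
  heuristic by construction (M + basic residues + hydrophobic h-region +
  A-S-A cleavage cassette); mutations inside it are class-preserving so a
  planted member can never lose its SP call.
* Planted cysteines are never mutated and substitutions never introduce
  new cysteines, so the planted C-pair is the only 9–11-spaced pair.
* Each CDS is embedded in random background DNA behind an in-frame
  upstream stop codon, making the open reading frame of a planted gene
  coincide exactly with its coding interval.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .famfilter import BASIC_RESIDUES, SMALL_RESIDUES
from .seqio import CODON_TABLE, IntervalAnnotation, SequenceRecord, reverse_complement

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_C = _AA20.replace("C", "")
_HYDROPHOBIC = "LIVF"
# SP h-region avoids V: V is both hydrophobic and "small", and a V at the
# core boundary could legitimise an earlier cleavage site than the planted one
_SP_HYDRO = "LIF"
#: synonymous codons per residue (stop handled separately)
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    _CODONS.setdefault(_aa, []).append(_codon)
_STOP_CODONS = _CODONS.pop("*")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of the planted peptide-family benchmark.

    Defaults are the package's standard benchmark conditions: 8 species of
    3 members each, ~10% per-site divergence from the ancestor, a quarter
    of members unannotated, and 40 short decoy proteins per species.
    """

    n_species: int = 8
    members_per_species: int = 3
    precursor_length_range: tuple[int, int] = (60, 120)
    sp_length: int = 25
    cys_gap_range: tuple[int, int] = (9, 11)
    substitution_prob: float = 0.1
    fraction_unannotated: float = 0.25
    decoys_per_species: int = 40
    decoy_length_range: tuple[int, int] = (40, 140)
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for lo, hi in (self.precursor_length_range, self.cys_gap_range,
                       self.decoy_length_range):
            if lo > hi:
                raise ValueError(f"range ({lo}, {hi}) not ordered")
        for p in (self.substitution_prob, self.fraction_unannotated):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.sp_length < 14:
            raise ValueError("sp_length must be >= 14")


@dataclass
class FamilyData:
    """Planted family output: ancestor, members, decoys and ground truth."""

    ancestor: SequenceRecord
    members: list[SequenceRecord]
    decoys: list[SequenceRecord]
    truth: pd.DataFrame
    spec: FamilySpec


@dataclass
class GenomeData:
    """Per-species genomes, annotation masks, and the augmented truth."""

    genomes: dict[str, SequenceRecord]
    annotations: list[IntervalAnnotation]
    truth: pd.DataFrame
    #: proteome records (planted members that are annotated, plus decoys)
    proteome: list[SequenceRecord] = field(default_factory=list)


def _species_names(n: int) -> list[str]:
    return [f"sp{i + 1}" for i in range(n)]


def _build_signal_peptide(rng: np.random.Generator, sp_length: int) -> str:
    """M + basic n-region + hydrophobic h-region + 'ASA' cleavage cassette."""
    n_basic = 2
    core_len = sp_length - 1 - n_basic - 3
    basic = "".join(rng.choice(list(BASIC_RESIDUES)) for _ in range(n_basic))
    core = "".join(rng.choice(list(_SP_HYDRO)) for _ in range(core_len))
    return "M" + basic + core + "ASA"


def _mutate_sp(sp: str, rng: np.random.Generator, p: float) -> str:
    """Class-preserving mutation of the signal peptide (M fixed)."""
    out = [sp[0]]
    for c in sp[1:]:
        if rng.random() < p:
            if c in BASIC_RESIDUES:
                c = str(rng.choice(list(BASIC_RESIDUES)))
            elif c in _SP_HYDRO:
                c = str(rng.choice(list(_SP_HYDRO)))
            elif c in SMALL_RESIDUES:
                c = str(rng.choice(["A", "G", "S", "T"]))
        out.append(c)
    return "".join(out)


def _strip_cys_motif(seq: str, rng: np.random.Generator,
                     min_gap: int = 9, max_gap: int = 11) -> str:
    """Destroy any C-x(min..max)-C spacing so decoys fail the motif filter."""
    chars = list(seq)
    while True:
        pos = [i for i, c in enumerate(chars) if c == "C"]
        hit = next(
            ((a, b) for a, b in zip(pos, pos[1:]) if min_gap <= b - a - 1 <= max_gap),
            None,
        )
        if hit is None:
            return "".join(chars)
        chars[hit[1]] = str(rng.choice(list(_AA_NO_C)))


def generate_family(spec: FamilySpec) -> FamilyData:
    """Plant a star-evolving secreted peptide family plus decoy proteins.

    Every member carries the ancestor's signal peptide (class-preserved
    under mutation) and exactly one C-x(g)-C motif, g drawn from
    ``spec.cys_gap_range``, in the C-terminal half of the precursor;
    cysteines are never mutated.  Decoys are random proteins scrubbed of
    any 9–11-spaced cysteine pair.
    """
    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.precursor_length_range
    total_len = int(rng.integers(lo, hi + 1))
    gap = int(rng.integers(spec.cys_gap_range[0], spec.cys_gap_range[1] + 1))
    motif_len = gap + 2
    if spec.sp_length + motif_len + 5 > total_len:
        raise ValueError(
            f"motif (len {motif_len}) plus signal peptide (len {spec.sp_length}) "
            f"does not fit a {total_len}-residue precursor"
        )
    sp = _build_signal_peptide(rng, spec.sp_length)
    mature_len = total_len - spec.sp_length
    mature = [str(rng.choice(list(_AA_NO_C))) for _ in range(mature_len)]
    # plant the cysteine pair in the C-terminal half of the precursor
    half = max(total_len // 2, spec.sp_length) - spec.sp_length
    cys1 = int(rng.integers(half, mature_len - motif_len + 1))
    mature[cys1] = "C"
    mature[cys1 + gap + 1] = "C"
    ancestor = SequenceRecord(
        id="ancestor", residues=sp + "".join(mature), species="",
        moltype="protein", source="seed",
    )
    cys_abs = {spec.sp_length + cys1, spec.sp_length + cys1 + gap + 1}

    members: list[SequenceRecord] = []
    rows = []
    for sp_name in _species_names(spec.n_species):
        for k in range(spec.members_per_species):
            new_sp = _mutate_sp(ancestor.residues[: spec.sp_length], rng,
                                spec.substitution_prob)
            body = []
            for i in range(spec.sp_length, total_len):
                c = ancestor.residues[i]
                if i not in cys_abs and rng.random() < spec.substitution_prob:
                    choices = [x for x in _AA_NO_C if x != c]
                    c = str(rng.choice(choices))
                body.append(c)
            rec = SequenceRecord(
                id=f"{sp_name}_fam{k + 1}", residues=new_sp + "".join(body),
                species=sp_name, moltype="protein", source="annotated",
            )
            members.append(rec)
            rows.append(dict(
                id=rec.id, species=sp_name, is_family=True, annotated=True,
                genome_id="", start=0, end=0, strand="+",
                mature_start=spec.sp_length + 1, mature_end=total_len,
            ))

    decoys: list[SequenceRecord] = []
    dlo, dhi = spec.decoy_length_range
    for sp_name in _species_names(spec.n_species):
        for k in range(spec.decoys_per_species):
            n = int(rng.integers(dlo, dhi + 1))
            seq = "".join(rng.choice(list(_AA20)) for _ in range(n))
            seq = _strip_cys_motif(seq, rng, *spec.cys_gap_range)
            decoys.append(SequenceRecord(
                id=f"{sp_name}_decoy{k + 1}", residues=seq, species=sp_name,
                moltype="protein", source="decoy",
            ))
    truth = pd.DataFrame(rows)
    return FamilyData(ancestor=ancestor, members=members, decoys=decoys,
                      truth=truth, spec=spec)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous-codon reverse translation, ATG start, one stop."""
    codons = ["ATG"]
    for aa in protein[1:]:
        codons.append(str(rng.choice(_CODONS[aa])))
    codons.append(str(rng.choice(_STOP_CODONS)))
    return "".join(codons)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(n))


def generate_genomes(family: FamilyData, gene_spacing: int = 150) -> GenomeData:
    """Embed every member's CDS in random background DNA per species.

    A global quota of ``round(fraction_unannotated * n_members)`` members,
    spread round-robin across species, is omitted from both the proteome
    and the annotation table while remaining in the genome; half of all
    genes land on the minus strand.  Each CDS is preceded in-frame by a
    stop codon so its ORF equals its coding interval exactly.
    """
    spec = family.spec
    rng = np.random.default_rng(spec.rng_seed + 1)
    truth = family.truth.copy()
    by_species: dict[str, list[SequenceRecord]] = {}
    for rec in family.members:
        by_species.setdefault(rec.species, []).append(rec)

    n_members = len(family.members)
    quota = int(round(spec.fraction_unannotated * n_members))
    unannotated: set[str] = set()
    # round-robin across species, k-th member of each species in turn
    order = [recs[k].id
             for k in range(spec.members_per_species)
             for recs in by_species.values()
             if k < len(recs)]
    unannotated.update(order[:quota])

    genomes: dict[str, SequenceRecord] = {}
    annotations: list[IntervalAnnotation] = []
    for sp_name, recs in by_species.items():
        genome_id = f"{sp_name}_chr1"
        parts: list[str] = [_random_dna(rng, gene_spacing)]
        cursor = gene_spacing
        for rec in recs:
            cds = _reverse_translate(rec.residues, rng)
            minus = bool(rng.random() < 0.5)
            # in-frame upstream stop pins the ORF to the coding interval
            guarded = "TAA" + cds
            insert = reverse_complement(guarded) if minus else guarded
            # plus: [TAA][CDS] -> CDS begins after the 3-nt guard
            # minus: revcomp puts the guard at the 3' end in plus coords
            cds_start = cursor + 3 + 1 if not minus else cursor + 1
            cds_end = cds_start + len(cds) - 1
            parts.append(insert)
            cursor += len(insert)
            parts.append(_random_dna(rng, gene_spacing))
            cursor += gene_spacing
            strand = "-" if minus else "+"
            idx = truth.index[truth["id"] == rec.id][0]
            truth.loc[idx, ["genome_id", "start", "end", "strand"]] = (
                genome_id, cds_start, cds_end, strand)
            if rec.id in unannotated:
                truth.loc[idx, "annotated"] = False
            else:
                annotations.append(IntervalAnnotation(
                    seq_id=genome_id, start=cds_start, end=cds_end,
                    strand=strand, feature=rec.id,
                ))
        genomes[sp_name] = SequenceRecord(
            id=genome_id, residues="".join(parts), species=sp_name,
            moltype="dna", source="annotated",
        )
    proteome = [r for r in family.members if r.id not in unannotated]
    proteome += family.decoys
    return GenomeData(genomes=genomes, annotations=annotations, truth=truth,
                      proteome=proteome)


def generate_expression(truth: pd.DataFrame, decoy_ids: Sequence[str],
                        induction_log2fc: float = 4.0, noise_sd: float = 0.5,
                        rng_seed: int = 1,
                        column: str = "flg22_90min") -> pd.DataFrame:
    """Expression table: induced family transcripts, null decoys.

    Annotated family transcripts draw log2FC ~ Normal(induction, sd);
    decoys ~ Normal(0, sd).  Unannotated members have no transcript model
    and therefore no row, mirroring real annotation gaps.
    """
    if induction_log2fc <= 0:
        raise ValueError("induction_log2fc must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(rng_seed)
    rows = []
    fam = truth[truth["is_family"] & truth["annotated"]]
    for gene_id in fam["id"]:
        rows.append((gene_id, induction_log2fc + rng.normal(0.0, noise_sd)
                     if noise_sd else induction_log2fc))
    for gene_id in decoy_ids:
        rows.append((gene_id, rng.normal(0.0, noise_sd) if noise_sd else 0.0))
    return pd.DataFrame(rows, columns=["gene_id", column])


# ---------------------------------------------------------------------------
# Receptor-kinase family


@dataclass
class RkData:
    members: list[SequenceRecord]
    decoys: list[SequenceRecord]
    truth: pd.DataFrame


def _lrr_unit(rng: np.random.Generator) -> str:
    """One LxxLxLxxNxL repeat with random x positions (non-aliphatic x)."""
    fill = [c for c in _AA20 if c not in "LIVFC"]
    out = []
    for k, c in enumerate("LXXLXLXXNXL"):
        if c == "X":
            out.append(str(rng.choice(fill)))
        else:
            out.append(c)
    return "".join(out)


def generate_rk_family(n_species: int = 4, members_per_species: int = 2,
                       n_lrr: int = 8, rng_seed: int = 11,
                       n_decoys: int = 0,
                       decoy_length_range: tuple[int, int] = (500, 700)) -> RkData:
    """Plant an LRR receptor-kinase family (plus optional long decoys).

    Each member: signal peptide, LRR ectodomain (``n_lrr`` tandem repeats
    plus flanking random sequence), one hydrophobic transmembrane helix,
    and a kinase domain carrying the ordered GxGxxG / VAIK-lysine / HRD /
    DFG motifs; total length >= 500.  Decoys are random proteins of
    receptor length.
    """
    if members_per_species < 1:
        raise ValueError("members_per_species must be >= 1")
    if n_lrr < 4:
        raise ValueError("n_lrr must be >= 4")
    rng = np.random.default_rng(rng_seed)
    sp_len = 25
    sp_region = _build_signal_peptide(rng, sp_len)
    ecto_pad = "".join(rng.choice(list(_AA_NO_C)) for _ in range(40))
    lrrs = "".join(_lrr_unit(rng) for _ in range(n_lrr))
    juxta = "".join(rng.choice(list("STQNDE")) for _ in range(15))
    tm_len = int(rng.integers(19, 24))
    tm = "".join(rng.choice(list(_HYDROPHOBIC)) for _ in range(tm_len))
    # kinase core with the ordered motif quartet and low-hydropathy filler
    filler = list("STQNDEGHKRP")
    def fill(n: int) -> str:
        return "".join(rng.choice(filler) for _ in range(n))
    kinase = (
        fill(12) + "GSGSFG" + fill(10) + "K" +
        fill(60) + "HRD" + fill(25) + "DFG" + fill(120)
    )
    ancestor_body = sp_region + ecto_pad + lrrs + juxta + tm + kinase
    deficit = 520 - len(ancestor_body)
    if deficit > 0:
        ancestor_body += fill(deficit)

    ecto_start = sp_len + 1
    tm_start = sp_len + len(ecto_pad) + len(lrrs) + len(juxta) + 1
    tm_end = tm_start + tm_len - 1
    kin_start = tm_end + 1

    members, rows = [], []
    for sp_name in _species_names(n_species):
        for k in range(members_per_species):
            # mutate only the x/filler positions, never motif anchors
            # mutate only residues that are never motif anchors (keeps the
            # conserved LRR N, HRD/DFG aspartates and G-loop intact)
            seq = list(ancestor_body)
            for i in range(sp_len, len(seq)):
                if seq[i] in "STQE" and rng.random() < 0.05:
                    seq[i] = str(rng.choice(list("STQE")))
            rec = SequenceRecord(
                id=f"{sp_name}_rk{k + 1}", residues="".join(seq),
                species=sp_name, moltype="protein", source="annotated",
            )
            members.append(rec)
            rows.append(dict(
                id=rec.id, species=sp_name, n_lrr=n_lrr, sp_end=sp_len,
                ecto_start=ecto_start, ecto_end=tm_start - 1,
                tm_start=tm_start, tm_end=tm_end,
                kinase_start=kin_start, kinase_end=len(seq),
            ))
    decoys = []
    dlo, dhi = decoy_length_range
    for k in range(n_decoys):
        n = int(rng.integers(dlo, dhi + 1))
        decoys.append(SequenceRecord(
            id=f"rkdecoy{k + 1}",
            residues="".join(rng.choice(list(_AA20)) for _ in range(n)),
            species="sp1", moltype="protein", source="decoy",
        ))
    return RkData(members=members, decoys=decoys, truth=pd.DataFrame(rows))
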