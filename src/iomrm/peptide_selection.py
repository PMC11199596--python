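"""Rule-based proteotypic peptide selection.

A surrogate peptide must identify exactly one protein, digest cleanly and
reproducibly, fly well in the mass spectrometer, and be free of sequence
features that change its mass or its yield between samples. This module
implements that filter chain:

* in silico fully tryptic digestion (cleave after K/R, never before P, zero
  missed cleavages);
* uniqueness against a proteome index (exact substring; Ile/Leu are treated
  as distinct residues);
* hard exclusions — chemically labile motifs (NG/NP deamidation sites,
  N-terminal Gln pyroglutamate formation), protein N-terminal peptides
  (co/post-translational processing), length outside 5-30 residues,
  hydrophobicity outside the 10-40 SSRCalc window, common sequence variants
  (minor allele frequency > 1%), and frequently modified sites;
* soft deprioritizations — Cys (alkylation variability), Met (oxidation),
  ragged ends (adjacent K/R at a cleavage boundary), protein C-terminal
  peptides;
* ranking of the surviving candidates by empirical observability
  (observation count, then median intensity), penalized by the number of
  deprioritizations, with the sequence as a deterministic final tiebreak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._ssrcalc_data import NT_WEIGHTS, RC, RC_NT, SSRCALC_VERSION

LENGTH_RANGE = (5, 30)
HYDROPHOBICITY_RANGE = (10.0, 40.0)
MAF_THRESHOLD = 0.01

HARD_RULES = frozenset(
    {
        "not_unique",
        "has_NG",
        "has_NP",
        "n_terminal_Q",
        "protein_n_terminal",
        "length_out_of_range",
        "hydrophobicity_out_of_range",
        "common_variant",
        "frequent_ptm",
    }
)
SOFT_RULES = frozenset({"contains_C", "contains_M", "ragged_end", "protein_c_terminal"})


@dataclass(frozen=True)
class DigestPeptide:
    """A fully tryptic peptide with its position in the parent protein."""

    protein_id: str
    sequence: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    is_n_terminal_peptide: bool = False
    is_c_terminal_peptide: bool = False
    has_ragged_end: bool = False


@dataclass
class CandidateFlags:
    peptide: DigestPeptide
    hard_exclusions: set[str] = field(default_factory=set)
    deprioritizations: set[str] = field(default_factory=set)
    hydrophobicity: float = float("nan")

    @property
    def selectable(self) -> bool:
        return not self.hard_exclusions


@dataclass(frozen=True)
class VariantAnnotation:
    protein_id: str
    position: int  # 1-based residue index
    minor_allele_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.minor_allele_frequency <= 1.0:
            raise ValueError("minor allele frequency must lie in [0, 1]")


@dataclass(frozen=True)
class ObservationEvidence:
    sequence: str
    observation_count: int
    median_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.observation_count < 0:
            raise ValueError("observation count must be >= 0")


def digest_tryptic(protein_sequence: str, protein_id: str = "protein") -> list[DigestPeptide]:
    """Fully tryptic in silico digest: cleave after K/R except before P.

    Zero missed cleavages. The returned peptides tile the protein exactly;
    N/C-terminal and ragged-end flags are set from the cleavage context.
    """
    seq = protein_sequence.strip().upper()
    if not seq:
        return []
    cut_after = [
        i for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    starts = [0] + [i + 1 for i in cut_after]
    ends = [i + 1 for i in cut_after] + [len(seq)]
    peptides = []
    for s, e in zip(starts, ends):
        prev_prev = seq[s - 2] if s >= 2 else ""
        nxt = seq[e] if e < len(seq) else ""
        # ragged end: a second K/R immediately inside either cleavage boundary
        ragged = (prev_prev in "KR") or (nxt in "KR")
        peptides.append(
            DigestPeptide(
                protein_id=protein_id,
                sequence=seq[s:e],
                start=s + 1,
                end=e,
                is_n_terminal_peptide=(s == 0),
                is_c_terminal_peptide=(e == len(seq)),
                has_ragged_end=ragged,
            )
        )
    return peptides


def ssrcalc_hydrophobicity(sequence: str) -> float:
    """Additive SSRCalc-style hydrophobicity index (100 A / TFA scale).

    H = KL * [ sum_i RC(aa_i) + sum_{j<=3} w_j * (RC_NT(aa_j) - RC(aa_j)) ]
    with length scaling KL = 1 - 0.055*(10-N) for short peptides,
    KL = 1/(1 + 0.027*(N-20)) for long ones, and damping of the top of the
    scale (H > 38 is compressed by 30%). Deterministic; raises on
    nonstandard residues.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    for aa in seq:
        if aa not in RC:
            raise ValueError(f"nonstandard residue {aa!r} in {sequence!r}")
    total = sum(RC[aa] for aa in seq)
    for w, aa in zip(NT_WEIGHTS, seq[:3]):
        total += w * (RC_NT[aa] - RC[aa])
    n = len(seq)
    if n < 10:
        kl = 1.0 - 0.055 * (10 - n)
    elif n > 20:
        kl = 1.0 / (1.0 + 0.027 * (n - 20))
    else:
        kl = 1.0
    h = kl * total
    if h > 38.0:
        h = h - 0.3 * (h - 38.0)
    return h


class ProteomeIndex:
    """Exact substring lookup across a set of protein sequences.

    Uniqueness is judged on exact residue identity — Ile and Leu are NOT
    collapsed. A peptide is unique when it occurs in exactly one protein
    (multiple occurrences within that protein still count as unique to it).
    """

    def __init__(self, proteins: Mapping[str, str]):
        self._proteins = {pid: s.strip().upper() for pid, s in proteins.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteomeIndex":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def proteins_containing(self, peptide: str) -> list[str]:
        pep = peptide.upper()
        return [pid for pid, seq in self._proteins.items() if pep in seq]

    def is_unique_to(self, peptide: str, protein_id: str) -> bool:
        hits = self.proteins_containing(peptide)
        return hits == [protein_id]

    def items(self):
        return self._proteins.items()


def evaluate_candidate(
    peptide: DigestPeptide,
    proteome_index: ProteomeIndex | None = None,
    variants: Iterable[VariantAnnotation] = (),
    ptm_annotations: Iterable[tuple[str, int]] = (),
    length_range: tuple[int, int] = LENGTH_RANGE,
    hydrophobicity_range: tuple[float, float] = HYDROPHOBICITY_RANGE,
    maf_threshold: float = MAF_THRESHOLD,
) -> CandidateFlags:
    """Apply every selection rule to one digest peptide; returns flags only.

    Nothing is silently dropped: a peptide failing a rule gets that rule in
    ``hard_exclusions`` (or ``deprioritizations``). The result is a pure
    function of the inputs.
    """
    seq = peptide.sequence
    flags = CandidateFlags(peptide=peptide)

    if proteome_index is not None and not proteome_index.is_unique_to(seq, peptide.protein_id):
        flags.hard_exclusions.add("not_unique")
    if "NG" in seq:
        flags.hard_exclusions.add("has_NG")
    if "NP" in seq:
        flags.hard_exclusions.add("has_NP")
    if seq.startswith("Q"):
        flags.hard_exclusions.add("n_terminal_Q")
    if peptide.is_n_terminal_peptide:
        flags.hard_exclusions.add("protein_n_terminal")
    if not (length_range[0] <= len(seq) <= length_range[1]):
        flags.hard_exclusions.add("length_out_of_range")
    else:
        try:
            flags.hydrophobicity = ssrcalc_hydrophobicity(seq)
            lo, hi = hydrophobicity_range
            if not (lo <= flags.hydrophobicity <= hi):
                flags.hard_exclusions.add("hydrophobicity_out_of_range")
        except ValueError:
            flags.hard_exclusions.add("hydrophobicity_out_of_range")

    for v in variants:
        if v.protein_id == peptide.protein_id and peptide.start <= v.position <= peptide.end:
            if v.minor_allele_frequency > maf_threshold:
                flags.hard_exclusions.add("common_variant")
    for pid, pos in ptm_annotations:
        if pid == peptide.protein_id and peptide.start <= pos <= peptide.end:
            flags.hard_exclusions.add("frequent_ptm")

    if "C" in seq:
        flags.deprioritizations.add("contains_C")
    if "M" in seq:
        flags.deprioritizations.add("contains_M")
    if peptide.has_ragged_end:
        flags.deprioritizations.add("ragged_end")
    if peptide.is_c_terminal_peptide:
        flags.deprioritizations.add("protein_c_terminal")
    return flags


def rank_candidates(
    flags_list: Sequence[CandidateFlags],
    evidence: Iterable[ObservationEvidence] = (),
) -> list[CandidateFlags]:
    """Order selectable candidates by empirical observability.

    Sort key: observation count (desc), median intensity (desc),
    deprioritization count (asc), then sequence (asc) as a deterministic
    final tiebreak. Candidates with no evidence count as zero observations.
    Excluded candidates are absent from the ranking but keep their flag
    ledger in ``flags_list``.
    """
    ev = {e.sequence: e for e in evidence}

    def key(f: CandidateFlags):
        e = ev.get(f.peptide.sequence)
        count = e.observation_count if e else 0
        intensity = e.median_intensity if e else 0.0
        return (-count, -intensity, len(f.deprioritizations), f.peptide.sequence)

    return sorted((f for f in flags_list if f.selectable), key=key)


def select_peptides(
    proteome: Mapping[str, str] | ProteomeIndex,
    variants: Iterable[VariantAnnotation] = (),
    ptm_annotations: Iterable[tuple[str, int]] = (),
    evidence: Iterable[ObservationEvidence] = (),
) -> pd.DataFrame:
    """End-to-end selection: digest every protein, flag, rank; full ledger.

    Returns one row per digest peptide with its flags, hydrophobicity, and
    (for selectable peptides) its within-protein rank.
    """
    index = proteome if isinstance(proteome, ProteomeIndex) else ProteomeIndex(proteome)
    evidence = list(evidence)
    variants = list(variants)
    ptm_annotations = list(ptm_annotations)
    rows = []
    for protein_id, seq in index.items():
        flags = [
            evaluate_candidate(p, index, variants, ptm_annotations)
            for p in digest_tryptic(seq, protein_id)
        ]
        ranked = rank_candidates(flags, evidence)
        order = {id(f): i + 1 for i, f in enumerate(ranked)}
        for f in flags:
            rows.append(
                {
                    "protein_id": protein_id,
                    "sequence": f.peptide.sequence,
                    "start": f.peptide.start,
                    "end": f.peptide.end,
                    "selectable": f.selectable,
                    "rank": order.get(id(f)),
                    "hydrophobicity": f.hydrophobicity,
                    "ssrcalc_version": SSRCALC_VERSION,
                    "hard_exclusions": ";".join(sorted(f.hard_exclusions)),
                    "deprioritizations": ";".join(sorted(f.deprioritizations)),
                }
            )
    return pd.DataFrame(rows)
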