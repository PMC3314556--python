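"""Reciprocal-smallest-distance (RSD) orthology and comparative-genomics calls.

Pairwise proteome comparison built on exhaustive global alignment
(BLOSUM62, affine gaps) with a Karlin-Altschul e-value analog. A pair
(a, b) is called orthologous when each is the other's smallest-divergence
hit passing the e-value and divergence thresholds, after removing records
that are too short or flagged as mobile-element / secondary-metabolite
genes. On top of the ortholog matrix sit the two comparative-genomics
screens: genes uniquely shared by the two target genomes
(:func:`candidate_gained_genes`) and reference genes retained across a
broad panel but missing from both targets (:func:`candidate_lost_genes`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinRecord",
    "AlignmentResult",
    "ScreenConfig",
    "OrthologMatrix",
    "align_pair",
    "rsd_orthologs",
    "candidate_gained_genes",
    "candidate_lost_genes",
    "residue_composition",
    "read_fasta_proteome",
    "write_fasta_proteome",
]

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_ACIDIC = set("DE")
_HYDROPHOBIC = set("AVLIMFWC")


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated protein sequence from a genome."""

    id: str
    genome: str
    sequence: str
    product: str = "hypothetical protein"
    excluded: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _AA20 - {"X"}
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    bitscore: float
    evalue_analog: float
    divergence: float
    aligned_length: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.divergence <= 1.0
        assert self.evalue_analog >= 0.0


@dataclass(frozen=True)
class ScreenConfig:
    """Every numeric threshold of the screen, in one place.

    Defaults mirror the published pipeline: RSD e-value < 1e-5 with at
    most 50% divergence over the entire alignment, a 350-aa minimum
    ortholog length, presence in >= 24 of a 27-genome panel for loss
    calls, <= 25 Actinobacterial species in the decisive gene-tree clade,
    and top-100 homolog lists filtered at e-value < 1e-5 and 50% length.
    """

    evalue_max: float = 1e-5
    divergence_max: float = 0.50
    min_length: int = 350
    min_panel_presence: int = 24
    panel_size: int = 27
    actino_clade_max: int = 25
    top_hits: int = 100
    blast_evalue_max: float = 1e-5
    min_hit_len_frac: float = 0.50
    # Karlin-Altschul gapped parameters for BLOSUM62 with open 11 / extend 1
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    gap_open: float = -11.0
    gap_extend: float = -1.0
    # ambiguity switches (see docs/methods.md)
    kimura_correction: bool = False
    actino_count_scope: str = "clade"  # or "tree"
    majority_mode: str = "per_clade"  # or "pooled"

    def __post_init__(self) -> None:
        if self.min_panel_presence > self.panel_size:
            raise ValueError("min_panel_presence cannot exceed panel_size")
        for name in ("evalue_max", "divergence_max", "min_length",
                     "min_panel_presence", "top_hits", "blast_evalue_max",
                     "min_hit_len_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


_ALIGNER_CACHE: dict[tuple[float, float], Align.PairwiseAligner] = {}


def _aligner(cfg: ScreenConfig) -> Align.PairwiseAligner:
    key = (cfg.gap_open, cfg.gap_extend)
    if key not in _ALIGNER_CACHE:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score = cfg.gap_open
        aligner.extend_gap_score = cfg.gap_extend
        _ALIGNER_CACHE[key] = aligner
    return _ALIGNER_CACHE[key]


def align_pair(
    a: ProteinRecord, b: ProteinRecord, cfg: Optional[ScreenConfig] = None
) -> AlignmentResult:
    """Global alignment of two proteins with divergence and e-value analog.

    Divergence is the fraction of non-identical columns over the entire
    alignment, gap columns counted as mismatches. The e-value analog is
    the Karlin-Altschul expectation K*m*n*exp(-lambda*S) over the product
    of the two sequence lengths; an optional Kimura-style correction
    (-ln(1 - d - d^2/5)) can replace raw divergence for thresholding.
    """
    cfg = cfg or ScreenConfig()
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    seq_a = a.sequence.replace("X", "A")  # X has no BLOSUM62 row here
    seq_b = b.sequence.replace("X", "A")
    alignment = _aligner(cfg).align(seq_a, seq_b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    divergence = 1.0 - counts.identities / columns
    if cfg.kimura_correction and divergence < 0.85:
        divergence = min(1.0, -math.log(1.0 - divergence - 0.2 * divergence**2))
    score = float(alignment.score)
    bitscore = (cfg.ka_lambda * score - math.log(cfg.ka_k)) / math.log(2.0)
    evalue = cfg.ka_k * len(seq_a) * len(seq_b) * math.exp(-cfg.ka_lambda * score)
    return AlignmentResult(
        score=score,
        bitscore=bitscore,
        evalue_analog=evalue,
        divergence=divergence,
        aligned_length=int(columns),
    )


@dataclass(frozen=True)
class OrthologMatrix:
    """Ortholog calls for one ordered genome pair."""

    genome_a: str
    genome_b: str
    pairs: Mapping[str, str]  # gene id in A -> ortholog id in B
    config: ScreenConfig = field(default_factory=ScreenConfig)

    def transpose(self) -> "OrthologMatrix":
        return OrthologMatrix(
            genome_b=self.genome_a,
            genome_a=self.genome_b,
            pairs={b: a for a, b in self.pairs.items()},
            config=self.config,
        )


def _screenable(records: Iterable[ProteinRecord], cfg: ScreenConfig) -> list[ProteinRecord]:
    return [r for r in records if not r.excluded and r.length >= cfg.min_length]


def rsd_orthologs(
    genome_a: Sequence[ProteinRecord],
    genome_b: Sequence[ProteinRecord],
    cfg: Optional[ScreenConfig] = None,
) -> OrthologMatrix:
    """Reciprocal smallest-distance ortholog calls between two proteomes.

    (a, b) is orthologous iff b is a's smallest-divergence hit passing
    ``evalue_max`` and ``divergence_max``, and reciprocally. Excluded and
    short records are dropped before calling. Ties break on higher score,
    then lexicographic id, so results are deterministic.
    """
    cfg = cfg or ScreenConfig()
    if not genome_a or not genome_b:
        raise ValueError("both genomes must be nonempty")
    recs_a = _screenable(genome_a, cfg)
    recs_b = _screenable(genome_b, cfg)
    name_a = genome_a[0].genome
    name_b = genome_b[0].genome
    if not recs_a or not recs_b:
        return OrthologMatrix(name_a, name_b, {}, cfg)

    hits: dict[tuple[str, str], AlignmentResult] = {}
    for ra in recs_a:
        for rb in recs_b:
            hits[(ra.id, rb.id)] = align_pair(ra, rb, cfg)

    def best_partner(rec, partners, key):
        candidates = []
        for p in partners:
            res = hits[key(rec, p)]
            if res.evalue_analog < cfg.evalue_max and res.divergence <= cfg.divergence_max:
                candidates.append((res.divergence, -res.score, p.id))
        if not candidates:
            return None
        return min(candidates)[2]

    best_a = {
        ra.id: best_partner(ra, recs_b, lambda a, b: (a.id, b.id)) for ra in recs_a
    }
    best_b = {
        rb.id: best_partner(rb, recs_a, lambda b, a: (a.id, b.id)) for rb in recs_b
    }
    pairs = {
        a_id: b_id
        for a_id, b_id in best_a.items()
        if b_id is not None and best_b.get(b_id) == a_id
    }
    return OrthologMatrix(name_a, name_b, pairs, cfg)


def candidate_gained_genes(
    targets: Sequence[Sequence[ProteinRecord]],
    panel: Sequence[Sequence[ProteinRecord]],
    cfg: Optional[ScreenConfig] = None,
) -> list[str]:
    """Genes unique to both target genomes.

    Returns ids (from the first target) of genes with an RSD ortholog in
    the second target and no RSD ortholog in any panel genome from either
    target's side.
    """
    cfg = cfg or ScreenConfig()
    if len(targets) != 2:
        raise ValueError("exactly two target genomes required")
    target_names = {t[0].genome for t in targets}
    panel_names = {g[0].genome for g in panel}
    if target_names & panel_names:
        raise ValueError(
            f"targets overlap panel: {sorted(target_names & panel_names)}"
        )
    a, b = targets
    between = rsd_orthologs(a, b, cfg)
    shared = dict(between.pairs)
    if not shared:
        return []
    hit_in_panel_a: set[str] = set()
    hit_in_panel_b: set[str] = set()
    for genome in panel:
        hit_in_panel_a |= set(rsd_orthologs(a, genome, cfg).pairs)
        hit_in_panel_b |= set(rsd_orthologs(b, genome, cfg).pairs)
    return sorted(
        a_id
        for a_id, b_id in shared.items()
        if a_id not in hit_in_panel_a and b_id not in hit_in_panel_b
    )


def candidate_lost_genes(
    reference: Sequence[ProteinRecord],
    panel: Sequence[Sequence[ProteinRecord]],
    targets: Sequence[Sequence[ProteinRecord]],
    cfg: Optional[ScreenConfig] = None,
) -> list[str]:
    """Reference genes broadly retained in the panel but absent from both targets."""
    cfg = cfg or ScreenConfig()
    ref_name = reference[0].genome
    if ref_name in {t[0].genome for t in targets}:
        raise ValueError("reference genome must not be a target")
    if len(panel) < cfg.min_panel_presence:
        raise ValueError(
            f"panel of {len(panel)} genomes cannot satisfy presence in "
            f">= {cfg.min_panel_presence}"
        )
    presence: dict[str, int] = {}
    for genome in panel:
        for ref_id in rsd_orthologs(reference, genome, cfg).pairs:
            presence[ref_id] = presence.get(ref_id, 0) + 1
    in_targets: set[str] = set()
    for target in targets:
        in_targets |= set(rsd_orthologs(reference, target, cfg).pairs)
    return sorted(
        ref_id
        for ref_id, n in presence.items()
        if n >= cfg.min_panel_presence and ref_id not in in_targets
    )


def residue_composition(p: ProteinRecord) -> tuple[float, float]:
    """(acidic fraction D+E, hydrophobic fraction A/V/L/I/M/F/W/C)."""
    if not p.sequence:
        raise ValueError("empty sequence")
    n = len(p.sequence)
    acidic = sum(1 for c in p.sequence if c in _ACIDIC)
    hydrophobic = sum(1 for c in p.sequence if c in _HYDROPHOBIC)
    return acidic / n, hydrophobic / n


def read_fasta_proteome(
    path: str | Path,
    genome: str,
    annotations: Optional[Mapping[str, Mapping]] = None,
) -> list[ProteinRecord]:
    """Read one genome's proteins from FASTA, joining optional annotations.

    ``annotations`` maps record id -> {"product": ..., "excluded": ...}.
    """
    records = []
    for seq in SeqIO.parse(str(path), "fasta"):
        meta = dict(annotations.get(seq.id, {})) if annotations else {}
        records.append(
            ProteinRecord(
                id=seq.id,
                genome=genome,
                sequence=str(seq.seq).upper(),
                product=str(meta.get("product", "hypothetical protein")),
                excluded=bool(meta.get("excluded", False)),
            )
        )
    return records


def write_fasta_proteome(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id} {r.product}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")
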