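"""Pairwise sequence comparison and binding-site conservation mapping.

Global (Needleman-Wunsch) alignment of two protein sequences with affine
gap penalties and BLOSUM62 scoring, reporting percent identity and percent
similarity, plus mapping of named binding-site residues (e.g. F185, G186,
T211, M291 of mouse TREK1) onto their aligned counterparts in a second
sequence — the machinery behind cross-ortholog/paralog conservation
statements such as "F185 in TREK1 aligns to a leucine in TRAAK".

Scoring defaults follow EMBOSS needle (BLOSUM62, gap open 10, gap extend
0.5, end gaps free): a gap of length L costs ``open + L * extend``.
Percent denominators use the full alignment length including gap columns
by default; "similarity" counts columns whose substitution score is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ScoringConfig",
    "PairwiseAlignmentResult",
    "SiteMap",
    "read_fasta",
    "global_align",
    "sweep_gap_penalties",
    "map_sites",
]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBZX")


@dataclass(frozen=True)
class ScoringConfig:
    """Affine-gap scoring in EMBOSS semantics (gap of length L costs
    ``gap_open + L * gap_extend``); end gaps are free by default."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    penalize_end_gaps: bool = False
    denominator: str = "alignment"  # or "shorter"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")
        if self.denominator not in ("alignment", "shorter"):
            raise ValueError("denominator must be 'alignment' or 'shorter'")


@dataclass
class PairwiseAlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float
    similarity_percent: float
    alignment_length: int
    config: ScoringConfig

    def degapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")

    def to_text(self, width: int = 60) -> str:
        """EMBOSS-style pairwise alignment block."""
        out = [
            f"# score: {self.score:.1f}",
            f"# identity: {self.identity_percent:.1f}%",
            f"# similarity: {self.similarity_percent:.1f}%",
            f"# length: {self.alignment_length}",
        ]
        for i in range(0, self.alignment_length, width):
            a = self.aligned_a[i:i + width]
            b = self.aligned_b[i:i + width]
            marks = "".join(
                "|" if x == y and x != "-" else
                (":" if x != "-" and y != "-" and _pair_score(self.config, x, y) > 0 else " ")
                for x, y in zip(a, b)
            )
            out += [a, marks, b, ""]
        return "\n".join(out)


def _validate(seq: str, name: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    for i, ch in enumerate(seq):
        if ch not in _VALID_AA:
            raise ValueError(
                f"{name}: invalid residue character {ch!r} at position {i + 1}"
            )
    return seq


def _matrix(cfg: ScoringConfig):
    return substitution_matrices.load(cfg.matrix)


def _pair_score(cfg: ScoringConfig, x: str, y: str) -> float:
    m = _matrix(cfg)
    try:
        return float(m[x, y])
    except KeyError:
        return float("-inf")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from a FASTA file as {record id: sequence}."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _make_aligner(cfg: ScoringConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(cfg)
    # EMBOSS gap of length L costs open + L*extend; Biopython charges
    # open_gap_score for the first gapped position and extend_gap_score for
    # each subsequent one.
    aligner.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    aligner.extend_gap_score = -cfg.gap_extend
    if not cfg.penalize_end_gaps:
        try:
            aligner.open_end_gap_score = 0.0
            aligner.extend_end_gap_score = 0.0
        except AttributeError:  # older Biopython naming
            aligner.end_open_gap_score = 0.0
            aligner.end_extend_gap_score = 0.0
    return aligner


def global_align(
    seq_a: str, seq_b: str, cfg: ScoringConfig | None = None
) -> PairwiseAlignmentResult:
    """Needleman-Wunsch global alignment with affine gaps.

    Identity = identical columns / denominator x 100; similarity = columns
    with a positive substitution score / denominator x 100.  The
    denominator is the alignment length including gap columns (or the
    shorter input length when ``cfg.denominator == "shorter"``).
    """
    cfg = cfg or ScoringConfig()
    a = _validate(seq_a, "seq_a")
    b = _validate(seq_b, "seq_b")
    aligner = _make_aligner(cfg)
    alignment = aligner.align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    assert len(ga) == len(gb)
    m = _matrix(cfg)
    ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    simil = sum(
        1
        for x, y in zip(ga, gb)
        if x != "-" and y != "-" and float(m[x, y]) > 0
    )
    denom = len(ga) if cfg.denominator == "alignment" else min(len(a), len(b))
    return PairwiseAlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        score=float(alignment.score),
        identity_percent=100.0 * ident / denom,
        similarity_percent=100.0 * simil / denom,
        alignment_length=len(ga),
        config=cfg,
    )


def sweep_gap_penalties(
    seq_a: str,
    seq_b: str,
    opens: tuple[float, ...] = (8.0, 10.0, 12.0),
    extends: tuple[float, ...] = (0.5, 1.0),
    matrix: str = "BLOSUM62",
) -> pd.DataFrame:
    """Identity/similarity across a grid of affine gap penalties.

    Useful when the gap parameters behind a published identity figure are
    unstated: the sweep shows how sensitive the percentages are.
    """
    rows = []
    for go in opens:
        for ge in extends:
            cfg = ScoringConfig(matrix=matrix, gap_open=go, gap_extend=ge)
            res = global_align(seq_a, seq_b, cfg)
            rows.append(
                {
                    "gap_open": go,
                    "gap_extend": ge,
                    "identity_percent": res.identity_percent,
                    "similarity_percent": res.similarity_percent,
                    "score": res.score,
                    "alignment_length": res.alignment_length,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Binding-site conservation mapping
# ---------------------------------------------------------------------------

GAP = "-"

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class SiteMap:
    """Aligned counterparts of named reference residues.

    Each row pairs a reference residue label (e.g. "F185") with the residue
    occupying the same alignment column in the second sequence, or an
    explicit gap token.
    """

    table: pd.DataFrame  # columns: label, ref_residue, ref_position, other_residue, conserved, region

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _parse_label(label: str) -> tuple[str | None, int]:
    label = str(label).strip()
    if label and label[0].isalpha():
        if len(label) >= 4 and label[:3].upper() in _AA3TO1:
            return _AA3TO1[label[:3].upper()], int(label[3:])
        return label[0].upper(), int(label[1:])
    return None, int(label)


def map_sites(
    result: PairwiseAlignmentResult,
    labels: list[str],
    numbering_offset: int = 0,
    regions: dict[str, tuple[int, int]] | None = None,
) -> SiteMap:
    """Map reference residue labels to their aligned counterparts.

    ``numbering_offset`` is added to 1-based sequence positions to obtain
    residue numbers (zero when the reference sequence starts at residue 1).
    ``regions`` optionally annotates each site with a named span, e.g.
    ``{"TM2": (170, 195)}``.
    """
    ga, gb = result.aligned_a, result.aligned_b
    # alignment column of each reference position (1-based, ungapped)
    col_of: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ga):
        if ch != GAP:
            pos += 1
            col_of[pos] = col
    n_ref = pos

    rows = []
    for label in labels:
        expected, number = _parse_label(label)
        seqpos = number - numbering_offset
        if not 1 <= seqpos <= n_ref:
            raise ValueError(
                f"site {label!r}: residue number {number} is outside the "
                f"reference sequence (1..{n_ref} after offset {numbering_offset})"
            )
        col = col_of[seqpos]
        ref_res = ga[col]
        if expected is not None and ref_res != expected:
            raise ValueError(
                f"site {label!r}: reference has {ref_res} at position {number}, "
                f"not {expected}"
            )
        other = gb[col]
        region = ""
        if regions:
            for name, (lo, hi) in regions.items():
                if lo <= number <= hi:
                    region = name
                    break
        rows.append(
            {
                "label": str(label),
                "ref_residue": ref_res,
                "ref_position": number,
                "other_residue": other,  # GAP token when deleted
                "conserved": other == ref_res,
                "region": region,
            }
        )
    return SiteMap(pd.DataFrame(rows))
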