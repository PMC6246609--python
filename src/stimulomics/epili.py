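"""Conductive type-IV pilin (e-pilus) screening.

Electrically conductive pili are built from PilA-type pilins whose mature
peptide is unusually rich in aromatic residues.  The screen: (1) locate the
class-III (prepilin-peptidase) cleavage site, (2) count aromatic residues
(F, Y, W, H) on the mature peptide, (3) align to a reference conductive
pilin and check seven essential aromatic columns, (4) call potential
conductivity when the aromatic percentage exceeds 9% and all essential
columns are aromatic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

AROMATIC = set("FYWH")
_PREPILIN_SECOND = set("FMLIVAS")
SEARCH_WINDOW = 40
SHORT_LONG_BOUNDARY = 80  # mature residues


@dataclass
class PilinAnnotation:
    protein_id: str
    cleavage_index: Optional[int]  # first mature residue, 0-based; None if uncleaved
    mature_length: int
    aromatic_count: int
    aromatic_pct: float
    essential_hits: Optional[int]
    conductivity_call: str  # potential_e_pilus | non_conductive | ambiguous
    pilin_type: str  # short | long
    uncleaved: bool = False


def mature_pilin(precursor: str) -> Optional[int]:
    """0-based index of the first mature residue, or None.

    Searches the first 40 residues for the type-IV prepilin motif
    G-[FMLIVAS]-x-x-x-E and cleaves after the G; the earliest candidate
    wins (logged when several occur).
    """
    if len(precursor) < 20:
        raise ValueError("pilin candidates must be at least 20 residues")
    candidates = []
    for i in range(min(SEARCH_WINDOW, len(precursor) - 5)):
        if (precursor[i] == "G" and precursor[i + 1] in _PREPILIN_SECOND
                and precursor[i + 5] == "E"):
            candidates.append(i + 1)
    if not candidates:
        return None
    if len(candidates) > 1:
        logger.info("multiple prepilin motifs at %s; using earliest", candidates)
    return candidates[0]


def aromatic_fraction(mature: str) -> Tuple[int, float]:
    """Count and percentage (1 d.p.) of F/Y/W/H residues."""
    if not mature:
        raise ValueError("empty mature sequence")
    count = sum(1 for a in mature if a in AROMATIC)
    return count, round(100.0 * count / len(mature), 1)


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def check_essential_columns(mature: str, reference: str,
                            positions: Sequence[int]) -> int:
    """Number of reference positions whose aligned query column is aromatic.

    Global alignment (BLOSUM62, affine gaps); a reference column aligned to
    a gap counts as a miss.
    """
    for p in positions:
        if not 0 <= p < len(reference):
            raise ValueError(f"essential position {p} outside reference")
    aligner = _global_aligner()
    aln = aligner.align(reference, mature)[0]
    ref_to_query: Dict[int, str] = {}
    for (rs, re_), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        for k in range(re_ - rs):
            ref_to_query[rs + k] = mature[qs + k]
    return sum(1 for p in positions if ref_to_query.get(p, "-") in AROMATIC)


def call_conductivity(aromatic_pct: float, essential_hits: Optional[int],
                      pct_threshold: float = 9.0,
                      required_hits: int = 7) -> str:
    """Decision table: e-pilus iff pct > threshold AND hits >= required."""
    if aromatic_pct <= pct_threshold:
        return "non_conductive"
    if essential_hits is not None and essential_hits >= required_hits:
        return "potential_e_pilus"
    return "ambiguous"


def annotate_pilin(protein_id: str, precursor: str, reference: str,
                   positions: Sequence[int], pct_threshold: float = 9.0,
                   required_hits: int = 7) -> PilinAnnotation:
    """Full pilin pipeline on one precursor sequence."""
    cleave = mature_pilin(precursor)
    uncleaved = cleave is None
    mature = precursor if uncleaved else precursor[cleave:]
    count, pct = aromatic_fraction(mature)
    hits = check_essential_columns(mature, reference, positions)
    return PilinAnnotation(
        protein_id=protein_id,
        cleavage_index=cleave,
        mature_length=len(mature),
        aromatic_count=count,
        aromatic_pct=pct,
        essential_hits=hits,
        conductivity_call=call_conductivity(pct, hits, pct_threshold,
                                            required_hits),
        pilin_type="short" if len(mature) <= SHORT_LONG_BOUNDARY else "long",
        uncleaved=uncleaved,
    )


def annotate_pilins(proteins: Dict[str, str], reference: str,
                    positions: Sequence[int], pct_threshold: float = 9.0,
                    required_hits: int = 7) -> List[PilinAnnotation]:
    return [
        annotate_pilin(pid, proteins[pid], reference, positions,
                       pct_threshold, required_hits)
        for pid in sorted(proteins)
    ]
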