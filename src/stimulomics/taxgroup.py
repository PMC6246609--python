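"""Species delineation for bin-genomes: ANIb, TETRA signatures, and
operational candidate species (OCS) grouping.

ANIb follows the fragment convention: the query is cut into consecutive
1020-bp pieces, each locally aligned to the subject (k-mer seeded, x-drop
extension); fragments aligning with >= 30% identity over >= 70% of their
length contribute, and the ANI is the mean identity of contributors,
averaged over both directions.  Two bins belong to the same OCS when
mean ANIb > 97% and the Pearson correlation of their tetranucleotide
z-score signatures (maximal-order Markov expectation) exceeds 0.99;
OCS are single-linkage components of that graph.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import networkx as nx
from scipy import stats

from .binning import _kmer_counts
from .simcom import revcomp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ANIb
# ---------------------------------------------------------------------------

_SEED_K = 15
_MATCH = 1
_MISMATCH = -2
_XDROP = 30


@dataclass
class ANIResult:
    query: str
    subject: str
    ani_qs: Optional[float]  # % identity, query fragments vs subject
    ani_sq: Optional[float]
    n_fragments_qs: int
    n_fragments_sq: int

    @property
    def mean_ani(self) -> Optional[float]:
        if self.ani_qs is None or self.ani_sq is None:
            return None
        return 0.5 * (self.ani_qs + self.ani_sq)


def _seed_index(seq: str, k: int = _SEED_K) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i: i + k], []).append(i)
    return index


def _extend(query: str, target: str, qp: int, tp: int, k: int,
            ) -> Tuple[int, int, int]:
    """Ungapped x-drop extension around an exact k-mer seed.

    Returns (aligned_length, matches, score) of the maximal-scoring HSP.
    """
    # right extension from the seed end
    score = k * _MATCH
    best = score
    matches = k
    best_right = (k, 0)  # (aligned beyond qp, extra matches)
    i, m = k, 0
    qi, ti = qp + k, tp + k
    while qi < len(query) and ti < len(target):
        score += _MATCH if query[qi] == target[ti] else _MISMATCH
        i += 1
        if query[qi] == target[ti]:
            m += 1
        if score > best:
            best = score
            best_right = (i, m)
        if best - score > _XDROP:
            break
        qi += 1
        ti += 1
    right_len, right_m = best_right
    # left extension from the seed start
    score = best
    best2 = score
    best_left = (0, 0)
    i, m = 0, 0
    qi, ti = qp - 1, tp - 1
    while qi >= 0 and ti >= 0:
        score += _MATCH if query[qi] == target[ti] else _MISMATCH
        i += 1
        if query[qi] == target[ti]:
            m += 1
        if score > best2:
            best2 = score
            best_left = (i, m)
        if best2 - score > _XDROP:
            break
        qi -= 1
        ti -= 1
    left_len, left_m = best_left
    total_len = left_len + right_len
    total_m = left_m + matches + right_m
    return total_len, total_m, best2


def _best_fragment_hit(frag: str, index: Dict[str, List[int]], target: str,
                       max_diagonals: int = 8) -> Optional[Tuple[int, int]]:
    """Best HSP (aligned_length, matches) of a fragment against one strand."""
    diag_support: Dict[int, Tuple[int, int, int]] = {}
    for qp in range(0, len(frag) - _SEED_K + 1):
        hits = index.get(frag[qp: qp + _SEED_K])
        if not hits:
            continue
        for tp in hits:
            d = tp - qp
            cnt, q0, t0 = diag_support.get(d, (0, qp, tp))
            diag_support[d] = (cnt + 1, q0, t0)
    if not diag_support:
        return None
    ranked = sorted(diag_support.items(), key=lambda kv: -kv[1][0])[:max_diagonals]
    best = None
    for _, (cnt, qp, tp) in ranked:
        alen, m, score = _extend(frag, target, qp, tp, _SEED_K)
        if best is None or score > best[2]:
            best = (alen, m, score)
    return (best[0], best[1]) if best else None


def _ani_one_direction(query: str, subject: str, frag_len: int,
                       min_identity: float, min_frag_cov: float,
                       ) -> Tuple[Optional[float], int]:
    fwd = _seed_index(subject)
    rc_subject = revcomp(subject)
    rev = _seed_index(rc_subject)
    identities = []
    n_frag = len(query) // frag_len
    for i in range(n_frag):
        frag = query[i * frag_len: (i + 1) * frag_len]
        best = None
        for index, target in ((fwd, subject), (rev, rc_subject)):
            hit = _best_fragment_hit(frag, index, target)
            if hit and (best is None or hit[1] > best[1]):
                best = hit
        if best is None:
            continue
        alen, m = best
        identity = 100.0 * m / alen
        coverage = alen / len(frag)
        if identity >= min_identity and coverage >= min_frag_cov:
            identities.append(identity)
    if not identities:
        return None, 0
    return float(np.mean(identities)), len(identities)


def anib(name_a: str, seq_a: str, name_b: str, seq_b: str,
         frag_len: int = 1020, min_identity: float = 30.0,
         min_frag_cov: float = 0.70) -> ANIResult:
    """Two-directional fragment-based average nucleotide identity."""
    if len(seq_a) < frag_len or len(seq_b) < frag_len:
        raise ValueError("both genomes must be at least one fragment long")
    qs, n_qs = _ani_one_direction(seq_a, seq_b, frag_len, min_identity, min_frag_cov)
    sq, n_sq = _ani_one_direction(seq_b, seq_a, frag_len, min_identity, min_frag_cov)
    return ANIResult(name_a, name_b, qs, sq, n_qs, n_sq)


# ---------------------------------------------------------------------------
# TETRA signatures
# ---------------------------------------------------------------------------

def _context_indices() -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For each 4-mer index w=n1n2n3n4: indices of n1n2n3, n2n3n4, n2n3."""
    w = np.arange(256)
    left3 = w // 4          # n1n2n3
    right3 = w % 64         # n2n3n4
    mid2 = (w // 4) % 16    # n2n3
    return left3, right3, mid2


_LEFT3, _RIGHT3, _MID2 = _context_indices()


def tetra_signature(seq: str) -> np.ndarray:
    """Tetranucleotide z-scores under the maximal-order Markov expectation.

    Counts pool the sequence and its reverse complement.  For word
    w = n1n2n3n4: E[w] = c(n1n2n3) c(n2n3n4) / c(n2n3) and
    Var[w] = E[w] ((c(n2n3)-c(n1n2n3))(c(n2n3)-c(n2n3n4))) / c(n2n3)^2;
    zero-variance words get z = 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) < 5000:
        logger.warning("tetra signature on short sequence (%d bp)", len(seq))
    rc = revcomp(seq)
    c4 = (_kmer_counts(seq, 4) + _kmer_counts(rc, 4)).astype(float)
    c3 = (_kmer_counts(seq, 3) + _kmer_counts(rc, 3)).astype(float)
    c2 = (_kmer_counts(seq, 2) + _kmer_counts(rc, 2)).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = c3[_LEFT3] * c3[_RIGHT3] / c2[_MID2]
        var = exp * ((c2[_MID2] - c3[_LEFT3]) * (c2[_MID2] - c3[_RIGHT3])
                     / c2[_MID2] ** 2)
        z = (c4 - exp) / np.sqrt(var)
    z[~np.isfinite(z)] = 0.0
    return z


def tetra_correlation(sig_a: np.ndarray, sig_b: np.ndarray) -> float:
    """Pearson correlation between two 256-entry TETRA signatures."""
    if np.std(sig_a) == 0 or np.std(sig_b) == 0:
        raise ValueError("constant signature: correlation undefined")
    r, _ = stats.pearsonr(sig_a, sig_b)
    return float(r)


#: Separator between concatenated contigs that contributes no k-mers
#: (non-ACGT characters are skipped by the counters and break word windows).
CONTIG_SEPARATOR = "N" * 10


def concat_bin(contig_seqs: Sequence[str]) -> str:
    return CONTIG_SEPARATOR.join(contig_seqs)


# ---------------------------------------------------------------------------
# OCS grouping
# ---------------------------------------------------------------------------

@dataclass
class OCSGroup:
    ocs_id: str
    members: List[str]
    is_pan_genome: bool = False
    core: Optional[str] = None
    substrains: List[str] = field(default_factory=list)


def group_ocs(bins: Sequence[str], ani_results: Sequence[ANIResult],
              correlations: Dict[Tuple[str, str], float],
              ani_threshold: float = 97.0,
              tetra_threshold: float = 0.99) -> List[OCSGroup]:
    """Single-linkage components of the (ANI > t1) AND (TETRA r > t2) graph."""
    g = nx.Graph()
    g.add_nodes_from(bins)
    corr = {}
    for (a, b), r in correlations.items():
        corr[(a, b)] = r
        corr[(b, a)] = r
    for res in ani_results:
        mean_ani = res.mean_ani
        r = corr.get((res.query, res.subject))
        if mean_ani is not None and r is not None:
            if mean_ani > ani_threshold and r > tetra_threshold:
                g.add_edge(res.query, res.subject)
    groups = []
    comps = sorted(nx.connected_components(g), key=lambda s: sorted(s)[0])
    for i, comp in enumerate(comps):
        groups.append(OCSGroup(f"OCS_{i + 1:03d}", sorted(comp)))
    return groups


def detect_pan_genome(group: OCSGroup, bin_links: Dict[Tuple[str, str], int],
                      coverage: Dict[str, np.ndarray],
                      additivity_tol: float = 0.25,
                      min_linked: int = 2) -> OCSGroup:
    """Flag a pan-genome: a core bin linked to >= 2 members whose coverage
    vector matches the sum of the linked members' coverages (relative L1)."""
    if len(group.members) < 2:
        return group
    links: Dict[str, List[str]] = {m: [] for m in group.members}
    for (a, b), n in bin_links.items():
        if n <= 0:
            continue
        if a in links and b in group.members:
            links[a].append(b)
        if b in links and a in group.members:
            links[b].append(a)
    for candidate in sorted(group.members):
        partners = sorted(set(links[candidate]) - {candidate})
        if len(partners) < min_linked:
            continue
        core_cov = coverage[candidate]
        summed = np.sum([coverage[p] for p in partners], axis=0)
        denom = np.abs(core_cov).sum()
        if denom == 0:
            continue
        rel_l1 = np.abs(core_cov - summed).sum() / denom
        if rel_l1 <= additivity_tol:
            group.is_pan_genome = True
            group.core = candidate
            group.substrains = partners
            return group
        logger.warning(
            "pan-genome candidate %s linked to %s but coverage non-additive "
            "(rel L1 %.3f > %.3f)", candidate, partners, rel_l1, additivity_tol)
    return group


def pairwise_ocs(bin_seqs: Dict[str, str], ani_threshold: float = 97.0,
                 tetra_threshold: float = 0.99,
                 frag_len: int = 1020) -> Tuple[List[ANIResult],
                                                Dict[Tuple[str, str], float],
                                                List[OCSGroup]]:
    """Convenience: all-pairs ANIb + TETRA and the resulting OCS grouping."""
    names = sorted(bin_seqs)
    sigs = {n: tetra_signature(bin_seqs[n]) for n in names}
    ani_results = []
    correlations = {}
    for a, b in itertools.combinations(names, 2):
        correlations[(a, b)] = tetra_correlation(sigs[a], sigs[b])
        try:
            ani_results.append(anib(a, bin_seqs[a], b, bin_seqs[b], frag_len=frag_len))
        except ValueError:
            logger.warning("skipping ANI for %s vs %s: genome too short", a, b)
    groups = group_ocs(names, ani_results, correlations,
                       ani_threshold, tetra_threshold)
    return ani_results, correlations, groups
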