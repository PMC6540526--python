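"""Repertoire diversity and clonality measurements.

For a repertoire with clone proportions :math:`p_1, \\dots, p_S`:

* richness :math:`S` — number of clones with positive count;
* Shannon entropy :math:`H = -\\sum_{p_i>0} p_i \\log p_i` (natural log by
  default, log2 by option);
* Simpson concentration :math:`\\lambda = \\sum p_i^2` and the Gini–Simpson
  index :math:`1-\\lambda` (the probability that two reads drawn at random
  come from different clones);
* species evenness — either the literal :math:`H/S` (default) or Pielou's
  :math:`H/\\log S`;
* top / second clone proportion — the largest and second-largest
  :math:`p_i`;
* total normalized count — clone reads per million total RNA-seq library
  reads (CPM);
* mean V-region identity — percent nucleotide identity of each clone to its
  best-matching germline V gene, averaged across clones; a surrogate for
  somatic hypermutation load.

Low evenness (a repertoire dominated by few clones) indicates clonal
restriction of the B-cell response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align

from ._errors import EmptyRepertoireError
from .types import GermlineReference, Repertoire

__all__ = [
    "DiversityProfile", "RankAbundance", "clone_proportions",
    "total_normalized_count", "shannon_entropy", "gini_simpson",
    "simpson_concentration", "species_evenness", "top_clone_proportion",
    "mean_v_region_identity", "clone_v_identities", "diversity_profile",
    "rank_abundance",
]


@dataclass
class DiversityProfile:
    """The per-(sample, chain) scalar measurement vector.

    ``evenness`` holds the configured mode's value; both modes are also kept
    explicitly because "entropy normalized by richness" is ambiguous and
    output tables report both.
    """

    sample_id: str
    chain: str
    total_count_norm: float
    richness: int
    shannon: float
    simpson_concentration: float
    gini_simpson: float
    evenness: float
    evenness_shannon_over_richness: float
    evenness_pielou: float
    top_clone_prop: float
    second_clone_prop: float | None
    mean_v_identity: float | None = None
    mean_v_mismatches: float | None = None


@dataclass
class RankAbundance:
    """Clones above a proportion threshold, ranked by descending abundance."""

    sample_id: str
    ranked: list[tuple[int, float, int]]  # (rank, proportion, count)


def clone_proportions(rep: Repertoire) -> np.ndarray:
    """Clone relative proportions p_i = count_i / total count."""
    counts = np.asarray(rep.counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise EmptyRepertoireError(
            f"repertoire {rep.sample_id}/{rep.chain} has no counted clones")
    return counts / counts.sum()


def total_normalized_count(rep: Repertoire) -> float:
    """Clone reads per million library reads (CPM)."""
    if rep.library_size <= 0:
        raise ValueError("library_size must be positive")
    return rep.total_count / rep.library_size * 1e6


def shannon_entropy(p: np.ndarray, base: str = "e") -> float:
    """Shannon entropy of a proportion vector; zero-proportion terms drop out."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    h = float(-np.sum(p * np.log(p)))
    if base == "2":
        h /= math.log(2)
    elif base != "e":
        raise ValueError(f"unknown log base {base!r}")
    # clamp the -0.0 that a single-clone vector produces
    return 0.0 if h == 0 else h


def simpson_concentration(p: np.ndarray) -> float:
    """Simpson's concentration λ = Σ p_i² (probability of same-clone draw)."""
    p = np.asarray(p, dtype=float)
    return float(np.sum(p * p))


def gini_simpson(p: np.ndarray) -> float:
    """Gini–Simpson index 1 − Σ p_i²."""
    return 1.0 - simpson_concentration(p)


def species_evenness(p: np.ndarray, mode: str = "shannon_over_richness",
                     base: str = "e") -> float:
    """Evenness of the proportion vector.

    ``shannon_over_richness`` divides entropy by the clone count S (the
    literal definition used for the prognostic measurement); ``pielou``
    divides by log S (0 by convention when S = 1).
    """
    p = np.asarray(p, dtype=float)
    s = int(np.sum(p > 0))
    if s < 1:
        raise EmptyRepertoireError("evenness undefined for an empty repertoire")
    h = shannon_entropy(p, base=base)
    if mode == "shannon_over_richness":
        return h / s
    if mode == "pielou":
        if s == 1:
            return 0.0
        denom = math.log(s) if base == "e" else math.log2(s)
        return h / denom
    raise ValueError(f"unknown evenness mode {mode!r}")


def top_clone_proportion(p: np.ndarray, k: int = 1) -> float | None:
    """k-th largest clone proportion (k = 1 or 2); None when S < k."""
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    p = np.sort(np.asarray(p, dtype=float))[::-1]
    if p.size < k:
        return None
    return float(p[k - 1])


# ---------------------------------------------------------------------------
# germline V-region identity (somatic hypermutation surrogate)

def _make_aligner() -> Align.PairwiseAligner:
    """Semi-global aligner: free end gaps, match +1 / mismatch −1,
    internal gap open −4 / extend −1."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_internal_gap_score = -4.0
    aligner.extend_internal_gap_score = -1.0
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _alignment_identity(alignment, query: str, target: str) -> tuple[float, int]:
    """Percent identity and mismatch count for one pairwise alignment.

    Columns counted are all alignment columns between the first and last
    aligned pair (so internal gaps count against identity). End overhangs
    present in only one sequence are free (they reflect length differences),
    but where *both* sequences dangle at the same end the overlap is counted
    as mismatched columns — otherwise a substitution at a terminal position
    would be silently shed into free end gaps and underreport hypermutation.
    """
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return 0.0, len(query)
    matches = 0
    aligned_len = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned_len += te - ts
        matches += sum(a == b for a, b in zip(target[ts:te], query[qs:qe]))
    t_span = t_blocks[-1][1] - t_blocks[0][0]
    q_span = q_blocks[-1][1] - q_blocks[0][0]
    internal_gaps = (t_span - aligned_len) + (q_span - aligned_len)
    left = min(t_blocks[0][0], q_blocks[0][0])
    right = min(len(target) - t_blocks[-1][1], len(query) - q_blocks[-1][1])
    columns = aligned_len + internal_gaps + left + right
    mismatches = columns - matches
    return 100.0 * matches / columns, mismatches


def clone_v_identities(rep: Repertoire, ref: GermlineReference,
                       ) -> list[tuple[str, str, float, int]]:
    """Best-germline identity per alignable clone.

    Returns (sequence, best_gene, identity_percent, mismatches) for each
    clone without ambiguous bases. When a clone carries a ``v_call`` present
    in the reference, only that gene is scored; otherwise every germline is
    tried and the best alignment score wins (ties to the lexicographically
    first gene name).
    """
    aligner = _make_aligner()
    out = []
    for clone in rep.clones:
        if clone.count == 0 or clone.has_ambiguous_bases:
            continue
        seq = clone.sequence.upper()
        if clone.v_call is not None and clone.v_call in ref.entries:
            candidates = [clone.v_call]
        else:
            candidates = sorted(ref.entries)
        best_score, best_gene, best_aln = -math.inf, None, None
        for gene in candidates:
            aln = aligner.align(ref.entries[gene], seq)[0]
            if aln.score > best_score:
                best_score, best_gene, best_aln = aln.score, gene, aln
        identity, mismatches = _alignment_identity(
            best_aln, seq, ref.entries[best_gene])
        out.append((clone.sequence, best_gene, identity, mismatches))
    return out


def mean_v_region_identity(rep: Repertoire, ref: GermlineReference,
                           weighted: bool = False) -> float | None:
    """Mean percent identity to the best germline V across unique clones.

    Unweighted by default; ``weighted=True`` weights clones by read count.
    Returns None when no clone is alignable (all contain N)."""
    details = clone_v_identities(rep, ref)
    if not details:
        return None
    idents = np.array([d[2] for d in details])
    if not weighted:
        return float(idents.mean())
    weights = np.array([c.count for c in rep.clones
                        if c.count > 0 and not c.has_ambiguous_bases], dtype=float)
    return float(np.average(idents, weights=weights))


def mean_v_region_mismatches(rep: Repertoire, ref: GermlineReference) -> float | None:
    """Mean mismatch count to the best germline V across unique clones."""
    details = clone_v_identities(rep, ref)
    if not details:
        return None
    return float(np.mean([d[3] for d in details]))


# ---------------------------------------------------------------------------

def diversity_profile(rep: Repertoire, ref: GermlineReference | None = None,
                      evenness_mode: str = "shannon_over_richness",
                      base: str = "e") -> DiversityProfile:
    """Compute the full measurement vector for one repertoire."""
    p = clone_proportions(rep)
    lam = simpson_concentration(p)
    ev_hs = species_evenness(p, "shannon_over_richness", base=base)
    ev_pielou = species_evenness(p, "pielou", base=base)
    evenness = ev_hs if evenness_mode == "shannon_over_richness" else ev_pielou
    identity = mismatches = None
    if ref is not None:
        details = clone_v_identities(rep, ref)
        if details:
            identity = float(np.mean([d[2] for d in details]))
            mismatches = float(np.mean([d[3] for d in details]))
    return DiversityProfile(
        sample_id=rep.sample_id,
        chain=rep.chain,
        total_count_norm=total_normalized_count(rep),
        richness=rep.richness,
        shannon=shannon_entropy(p, base=base),
        simpson_concentration=lam,
        gini_simpson=1.0 - lam,
        evenness=evenness,
        evenness_shannon_over_richness=ev_hs,
        evenness_pielou=ev_pielou,
        top_clone_prop=top_clone_proportion(p, 1),
        second_clone_prop=top_clone_proportion(p, 2),
        mean_v_identity=identity,
        mean_v_mismatches=mismatches,
    )


def rank_abundance(rep: Repertoire, min_prop: float = 0.01) -> RankAbundance:
    """Clones with relative proportion strictly above ``min_prop``, ranked by
    descending proportion; proportion ties break by sequence lexicographic
    order; ranks are contiguous from 1."""
    clones = [c for c in rep.clones if c.count > 0]
    if not clones:
        raise EmptyRepertoireError(
            f"repertoire {rep.sample_id}/{rep.chain} has no counted clones")
    total = sum(c.count for c in clones)
    entries = sorted(((c.count / total, c.sequence, c.count) for c in clones),
                     key=lambda t: (-t[0], t[1]))
    ranked = [(rank, prop, count)
              for rank, (prop, _seq, count) in enumerate(entries, start=1)
              if prop > min_prop]
    ranked = [(i + 1, prop, count) for i, (_r, prop, count) in enumerate(ranked)]
    return RankAbundance(sample_id=rep.sample_id, ranked=ranked)
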