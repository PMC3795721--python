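"""From positive probes to motifs and a binding consensus.

Because the probe library encodes every dsDNA hexamer class with a
unique, subset-free probe signature, a noise-free binder of one motif is
decoded *exactly* by signature containment. Real screens are noisy, so
the module also scores every motif class by discriminative enrichment of
its probes among the positives (exact hypergeometric tail, positives vs
the whole library — the closed 2080-class candidate space makes an
exhaustive exact test feasible where sequence-space tools resort to
heuristic motif discovery), and assembles the top classes into a
degenerate IUPAC consensus by greedy ungapped alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .core import (
    CanonicalMotif,
    canonical_representative,
    iupac_match,
    minimal_iupac,
    reverse_complement,
)
from .design import ProbeLibrary

__all__ = [
    "MotifSupport",
    "ConsensusModel",
    "decode_single",
    "enrich_motifs",
    "build_consensus",
    "consensus_matches",
]


def decode_single(
    positive_probes: set[str] | list[str], library: ProbeLibrary
) -> set[CanonicalMotif]:
    """Motif classes whose entire probe signature lies in the positive set.

    For a validator-clean library and a noise-free single-motif binder
    the result is exactly the bound motif. Candidates are collected from
    the positive probes only, so the scan is cheap.
    """
    positives = set(positive_probes)
    if not positives:
        return set()
    sig = library.signature_index()
    candidates: set[str] = set()
    probe_map = library.probe_map()
    from .core import forward_windows

    for pid in positives:
        probe = probe_map.get(pid)
        if probe is None or len(probe.variable_region) < library.k:
            continue
        for w in forward_windows(probe.variable_region, library.k):
            candidates.add(canonical_representative(w))
    return {
        CanonicalMotif(rep)
        for rep in candidates
        if sig.get(rep) and sig[rep] <= positives
    }


@dataclass
class MotifSupport:
    """Enrichment of one motif class among the positive probes."""

    motif: CanonicalMotif
    n_positive: int
    n_library: int
    enrichment_p: float


def enrich_motifs(
    positive_probes: set[str] | list[str], library: ProbeLibrary
) -> list[MotifSupport]:
    """Exact hypergeometric enrichment of every motif class.

    For a motif on ``K`` of the ``N`` library probes, the p-value is the
    upper tail of drawing its observed count among the ``n`` positives
    without replacement. Sorted ascending by p, ties by descending
    positive count then motif.
    """
    positives = set(positive_probes)
    if not positives:
        raise ValueError("no positive probes")
    sig = library.signature_index()
    library_ids = {p.probe_id for p in library.probes}
    n_total = len(library_ids)
    n_drawn = len(positives & library_ids)
    out = []
    for rep, probes in sig.items():
        k_lib = len(probes)
        k_pos = len(probes & positives)
        p = float(stats.hypergeom.sf(k_pos - 1, n_total, k_lib, n_drawn))
        out.append(
            MotifSupport(
                motif=CanonicalMotif(rep),
                n_positive=k_pos,
                n_library=k_lib,
                enrichment_p=min(p, 1.0),
            )
        )
    out.sort(key=lambda m: (m.enrichment_p, -m.n_positive, m.motif.representative))
    return out


def support_frame(supports: list[MotifSupport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": s.motif.representative,
                "reverse_complement": reverse_complement(s.motif.representative),
                "n_positive": s.n_positive,
                "n_library": s.n_library,
                "enrichment_p": s.enrichment_p,
            }
            for s in supports
        ]
    )


@dataclass
class ConsensusModel:
    """A derived binding consensus with its alignment evidence."""

    iupac: str
    count_matrix: pd.DataFrame = field(repr=False)  # 4 x L base counts
    supporting_motifs: list[MotifSupport] = field(default_factory=list)
    aligned: list[str] = field(default_factory=list)

    @property
    def n_aligned(self) -> int:
        return len(self.aligned)


def _best_alignment(anchor: str, motif: str, max_shift: int) -> tuple[str, int, int]:
    """Orientation and offset of ``motif`` against ``anchor`` maximizing
    identity in the overlap; larger overlap, smaller shift, forward
    orientation break ties. Offset is motif's start relative to anchor's."""
    best = None
    for oriented in (motif, reverse_complement(motif)):
        for off in range(-max_shift, max_shift + 1):
            lo = max(0, off)
            hi = min(len(anchor), off + len(oriented))
            overlap = hi - lo
            if overlap <= 0:
                continue
            ident = sum(
                anchor[i] == oriented[i - off] for i in range(lo, hi)
            )
            key = (
                ident,
                overlap,
                -abs(off),
                oriented == motif,  # prefer forward on full ties
            )
            if best is None or key > best[0]:
                best = (key, oriented, off, ident)
    assert best is not None
    return best[1], best[2], best[3]


def _pattern_enrichment(
    pattern: str, positives: set[str], library: ProbeLibrary
) -> float:
    """Hypergeometric enrichment of probes containing a window matching a
    degenerate pattern (either strand) among the positives."""
    from .core import forward_windows

    def matches(region: str) -> bool:
        if len(region) < len(pattern):
            return False
        for w in forward_windows(region, len(pattern)):
            if iupac_match(pattern, w) or iupac_match(
                pattern, reverse_complement(w)
            ):
                return True
        return False

    ids = [p.probe_id for p in library.probes]
    hit = {p.probe_id for p in library.probes if matches(p.variable_region)}
    n_total = len(ids)
    k_lib = len(hit)
    n_drawn = len(positives & set(ids))
    k_pos = len(hit & positives)
    return float(stats.hypergeom.sf(k_pos - 1, n_total, k_lib, n_drawn))


def _columns_to_consensus(aligned: list[str], offsets: list[int]) -> tuple[str, pd.DataFrame]:
    """IUPAC string and count matrix over the columns covered by every
    aligned sequence (the shared core)."""
    lo = max(offsets)
    hi = min(off + len(seq) for seq, off in zip(aligned, offsets))
    if hi <= lo:  # no shared core: fall back to the anchor frame
        lo, hi = 0, len(aligned[0])
        full = [
            (seq, off)
            for seq, off in zip(aligned, offsets)
            if off == 0 and len(seq) == hi
        ]
        aligned = [s for s, _ in full]
        offsets = [o for _, o in full]
    cols = []
    symbols = []
    for pos in range(lo, hi):
        bases = [seq[pos - off] for seq, off in zip(aligned, offsets)]
        symbols.append(minimal_iupac(bases))
        cols.append(
            {b: bases.count(b) for b in "ACGT"}
        )
    counts = pd.DataFrame(cols).T.fillna(0).astype(int)
    counts.columns = range(1, len(symbols) + 1)
    return "".join(symbols), counts


def build_consensus(
    supports: list[MotifSupport],
    positives: set[str] | None = None,
    library: ProbeLibrary | None = None,
    p_threshold: float = 0.01,
    max_shift: int = 2,
) -> ConsensusModel | None:
    """Greedy ungapped alignment of enriched motifs into an IUPAC consensus.

    Candidates below the enrichment threshold are merged in rank order
    onto the top motif (each tried in both orientations and small
    shifts); each column's symbol is the smallest base set covering the
    observed bases. When positives and the library are given, a candidate
    is only merged if the merged pattern's own discriminative enrichment
    does not degrade — this keeps hitchhiker motifs (whose probes fall in
    the positive set by coincidence) out of the consensus, the same
    generalization test discriminative motif finders apply. Returns None
    when no motif clears the threshold.
    """
    kept = [s for s in supports if s.enrichment_p <= p_threshold]
    if not kept:
        return None
    anchor = kept[0].motif.representative
    aligned = [anchor]
    offsets = [0]
    merged = [kept[0]]
    scoring = positives is not None and library is not None
    current_p = (
        _pattern_enrichment(anchor, positives, library) if scoring else None
    )
    for s in kept[1:]:
        oriented, off, _ = _best_alignment(anchor, s.motif.representative, max_shift)
        trial_aligned = aligned + [oriented]
        trial_offsets = offsets + [off]
        iupac, _ = _columns_to_consensus(list(trial_aligned), list(trial_offsets))
        if scoring:
            p = _pattern_enrichment(iupac, positives, library)
            if p > current_p:
                continue
            current_p = p
        aligned = trial_aligned
        offsets = trial_offsets
        merged.append(s)
    iupac, counts = _columns_to_consensus(aligned, offsets)
    return ConsensusModel(
        iupac=iupac, count_matrix=counts, supporting_motifs=merged, aligned=aligned
    )


def consensus_matches(consensus: str, target: str) -> bool:
    """Do two degenerate patterns describe the same element (either
    orientation), the derived one at least as specific as the target?"""
    from .core import iupac_expand, iupac_reverse_complement

    def subsumed(a: str, b: str) -> bool:
        return len(a) == len(b) and all(
            iupac_expand(x) <= iupac_expand(y) for x, y in zip(a, b)
        )

    return subsumed(consensus, target) or subsumed(
        iupac_reverse_complement(consensus), target
    )
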