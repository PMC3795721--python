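"""Design of unambiguous dsDNA probe libraries.

The designer distributes every dsDNA k-mer motif (2080 classes for
hexamers) over at most 384 microtiter wells so that the set of probes
containing a motif — its *signature* — identifies the motif uniquely.
A screen readout then decodes bound motifs purely from which wells light
up.

Per-probe constraints on the variable region:

(1) each directed k-mer occurs at most once,
(2) a k-mer and its reverse complement never co-occur,
(3) if two k-mers co-occur on one probe, their reverse complements do not
    co-occur on any probe (globally),
(4) at most one palindromic window per probe,
(5) masterstrand-derived probes are >= 15 bp,
(6) no probe exceeds 20 bp.

Construction runs in two steps. First, long *masterstrands* are grown
base by base with simultaneous placement of cut-marks that partition them
into probe-sized segments; a backtracking search keeps every segment
constraint-clean while steering elongation towards motifs that still need
probe placements. Second, a greedy completion step builds additional
probes (>= 11 bp) that place the motifs the masterstrands missed and
resolve any remaining ambiguity.

Beyond identical signatures, exact decoding also requires that no
signature be a *subset* of another (otherwise a binder of the larger-
signature motif is indistinguishable from a joint binder); the designer
maintains this subset-freeness invariant throughout, and the validator
and ambiguity report check it.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import pandas as pd

from .core import (
    DNA_BASES,
    canonical_representative,
    enumerate_motifs,
    forward_windows,
    reverse_complement,
)

__all__ = [
    "DesignConfig",
    "DesignError",
    "Masterstrand",
    "LibraryProbe",
    "ProbeLibrary",
    "AmbiguityReport",
    "ValidationReport",
    "check_segment",
    "check_pair_rule",
    "build_masterstrand",
    "cut_masterstrand",
    "find_ambiguities",
    "greedy_complete",
    "design_library",
    "validate_library",
]


class DesignError(RuntimeError):
    """Search failure; reseed or relax the configuration."""


@dataclass
class DesignConfig:
    """Parameters of a probe-library design run.

    Defaults are the published screen's: hexamer motifs, three 1600 bp
    masterstrands cut into 15-20 bp probes, a 384-well plate shared with
    32 control wells, and completion probes allowed down to 11 bp.
    """

    k: int = 6
    min_probe_len: int = 15
    max_probe_len: int = 20
    min_completion_probe_len: int = 11
    masterstrand_target_len: int = 1600
    n_masterstrands: int = 3
    well_budget: int = 384
    n_control_wells: int = 32
    seed: int = 0
    max_backtrack_steps: int = 1_000_000
    max_restarts: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 12:
            raise ValueError("k must be in 1..12")
        if self.min_probe_len > self.max_probe_len:
            raise ValueError("min_probe_len > max_probe_len")
        if self.min_completion_probe_len < self.k:
            raise ValueError("completion probes must hold at least one window")
        if self.masterstrand_target_len < self.max_probe_len:
            raise ValueError("masterstrand shorter than one probe")
        if self.well_budget <= self.n_control_wells:
            raise ValueError("well budget exhausted by controls")

    @property
    def max_library_probes(self) -> int:
        return self.well_budget - self.n_control_wells


@dataclass
class Masterstrand:
    """A designed strand plus the cut-marks partitioning it into segments."""

    sequence: str
    cut_marks: list[int]  # internal boundaries, strictly increasing, 0 < c < len

    def segments(self) -> list[str]:
        bounds = [0, *self.cut_marks, len(self.sequence)]
        return [self.sequence[a:b] for a, b in zip(bounds, bounds[1:])]


def cut_masterstrand(ms: Masterstrand) -> list[str]:
    """Variable regions obtained by cutting at the cut-marks, in order."""
    return ms.segments()


@dataclass
class LibraryProbe:
    probe_id: str
    variable_region: str
    source: str  # "masterstrand_<i>" or "completion"
    probe_class: str = "library"


@dataclass
class ProbeLibrary:
    """A designed (or loaded) probe set with its motif->probe signature index."""

    probes: list[LibraryProbe]
    k: int = 6
    masterstrands: list[Masterstrand] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate probe ids")

    def __len__(self) -> int:
        return len(self.probes)

    def probe_map(self) -> dict[str, LibraryProbe]:
        return {p.probe_id: p for p in self.probes}

    def signature_index(self) -> dict[str, frozenset[str]]:
        """Canonical motif representative -> frozenset of probe ids containing it."""
        sig: dict[str, set[str]] = {}
        for p in self.probes:
            if len(p.variable_region) < self.k:
                continue
            for w in forward_windows(p.variable_region, self.k):
                sig.setdefault(canonical_representative(w), set()).add(p.probe_id)
        return {rep: frozenset(s) for rep, s in sig.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "probe_id": p.probe_id,
                    "class": p.probe_class,
                    "variable_region": p.variable_region,
                    "source": p.source,
                }
                for p in self.probes
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, k: int = 6) -> "ProbeLibrary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        probes = [
            LibraryProbe(
                probe_id=row["probe_id"],
                variable_region=row["variable_region"],
                source=row.get("source", "loaded"),
                probe_class=row.get("class", "library"),
            )
            for _, row in df.iterrows()
        ]
        return cls(probes=probes, k=k)

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(p.variable_region), id=p.probe_id, description=p.source)
            for p in self.probes
        ]
        seqio_write(records, path, "fasta")


# ---------------------------------------------------------------------------
# Per-probe and global constraint checks
# ---------------------------------------------------------------------------


def check_segment(segment: str, k: int) -> list[tuple]:
    """Violations of the per-probe constraints (1), (2), (4) in one region.

    Returns ``(constraint_id, window_a, window_b)`` tuples; empty list for
    a clean segment (segments shorter than ``k`` trivially pass).
    """
    if len(segment) < k:
        return []
    violations: list[tuple] = []
    windows = forward_windows(segment, k)
    seen: dict[str, int] = {}
    palindromes: list[str] = []
    for w in windows:
        if w in seen:
            violations.append((1, w, w))
        rc = reverse_complement(w)
        if rc != w and rc in seen:
            violations.append((2, rc, w))
        if rc == w:
            if palindromes and w not in palindromes:
                violations.append((4, palindromes[0], w))
            palindromes.append(w)
        seen[w] = seen.get(w, 0) + 1
    return violations


def check_pair_rule(library: ProbeLibrary) -> list[tuple]:
    """Global constraint (3): co-occurring k-mer pairs vs their rc pairs.

    For every unordered pair of directed k-mers co-occurring as forward
    windows of some probe, reports every probe whose forward windows
    contain both reverse complements. Empty list means the rule holds.
    """
    k = library.k
    directed: dict[str, set[str]] = {}
    probe_wins: dict[str, list[str]] = {}
    for p in library.probes:
        if len(p.variable_region) < k:
            probe_wins[p.probe_id] = []
            continue
        wins = sorted(set(forward_windows(p.variable_region, k)))
        probe_wins[p.probe_id] = wins
        for w in wins:
            directed.setdefault(w, set()).add(p.probe_id)
    violations = []
    seen_keys = set()
    for pid, wins in probe_wins.items():
        for w, v in itertools.combinations(wins, 2):
            rcw, rcv = reverse_complement(w), reverse_complement(v)
            if rcw == w or rcv == v:  # rule targets non-palindromic pairs
                continue
            offenders = directed.get(rcw, set()) & directed.get(rcv, set())
            for q in offenders:
                key = (
                    frozenset((pid, q)),
                    frozenset(
                        (canonical_representative(w), canonical_representative(v))
                    ),
                )
                if key not in seen_keys:
                    seen_keys.add(key)
                    violations.append((pid, q, w, v))
    return violations


# ---------------------------------------------------------------------------
# Bookkeeping shared by masterstrand construction and greedy completion
# ---------------------------------------------------------------------------


class _Books:
    """Incremental motif/probe bookkeeping with O(1)-ish constraint checks."""

    def __init__(self, k: int):
        self.k = k
        self.sig: dict[str, set[str]] = {}  # class rep -> probe ids
        self.directed: dict[str, set[str]] = {}  # directed k-mer -> probe ids
        self.probe_windows: dict[str, set[str]] = {}
        self.probe_classes: dict[str, set[str]] = {}
        self.probe_pal: dict[str, int] = {}
        # remaining probe placements until every class reaches support 2
        self.deficit = 2 * len(_all_reps(k))
        # (k-1)-prefix -> number of directed k-mers of still-needed classes;
        # lets elongation look one base ahead into needed sequence space
        self.needed_prefix: dict[str, int] = {}
        for rep in _all_reps(k):
            rc = reverse_complement(rep)
            self.needed_prefix[rep[: k - 1]] = (
                self.needed_prefix.get(rep[: k - 1], 0) + 1
            )
            if rc != rep:
                self.needed_prefix[rc[: k - 1]] = (
                    self.needed_prefix.get(rc[: k - 1], 0) + 1
                )

    def _prefix_delta(self, rep: str, delta: int) -> None:
        rc = reverse_complement(rep)
        k = self.k
        self.needed_prefix[rep[: k - 1]] = (
            self.needed_prefix.get(rep[: k - 1], 0) + delta
        )
        if rc != rep:
            self.needed_prefix[rc[: k - 1]] = (
                self.needed_prefix.get(rc[: k - 1], 0) + delta
            )

    def support(self, rep: str) -> int:
        s = self.sig.get(rep)
        return len(s) if s else 0

    def open_probe(self, pid: str) -> None:
        self.probe_windows[pid] = set()
        self.probe_classes[pid] = set()
        self.probe_pal[pid] = 0

    def drop_probe(self, pid: str) -> None:
        assert not self.probe_windows[pid]
        del self.probe_windows[pid]
        del self.probe_classes[pid]
        del self.probe_pal[pid]

    def abort_probe(self, pid: str) -> None:
        """Retract every window of an in-progress probe and forget it."""
        for w in list(self.probe_windows[pid]):
            self.remove_window(pid, w)
        self.drop_probe(pid)

    def window_ok(self, pid: str, w: str) -> bool:
        """Can window ``w`` be added to probe ``pid`` without breaking
        constraints (1)(2)(4), the global pair rule (3), or signature
        subset-freeness?"""
        wins = self.probe_windows[pid]
        if w in wins:  # (1)
            return False
        rc = reverse_complement(w)
        if rc in wins:  # (2)
            return False
        if rc == w and self.probe_pal[pid] > 0:  # (4)
            return False
        # (3): pair {w, v} on pid vs {rc(w), rc(v)} elsewhere
        rcw_probes = self.directed.get(rc)
        if rcw_probes and rc != w:
            for v in wins:
                rcv = reverse_complement(v)
                if rcv == v:
                    continue
                other = self.directed.get(rcv)
                if other and rcw_probes & other:
                    return False
        # subset-freeness of signatures with support >= 2
        rep = w if w <= rc else rc
        cur = self.sig.get(rep)
        if cur is None:
            return True
        if pid in cur:  # cannot happen if (1)/(2) hold, defensive
            return False
        t = cur | {pid}
        if len(t) >= 2:
            for p in t:
                for rep2 in self.probe_classes.get(p, ()):
                    if rep2 == rep:
                        continue
                    s2 = self.sig.get(rep2)
                    if s2 is None or len(s2) < 2:
                        continue
                    if s2 <= t or t <= s2:
                        return False
        return True

    def add_window(self, pid: str, w: str) -> None:
        rc = reverse_complement(w)
        rep = w if w <= rc else rc
        self.probe_windows[pid].add(w)
        self.probe_classes[pid].add(rep)
        if rc == w:
            self.probe_pal[pid] += 1
        self.directed.setdefault(w, set()).add(pid)
        s = self.sig.setdefault(rep, set())
        if len(s) < 2:
            self.deficit -= 1
            if len(s) == 1:  # class just became satisfied
                self._prefix_delta(rep, -1)
        s.add(pid)

    def remove_window(self, pid: str, w: str) -> None:
        rc = reverse_complement(w)
        rep = w if w <= rc else rc
        self.probe_windows[pid].discard(w)
        if rc == w:
            self.probe_pal[pid] -= 1
        d = self.directed[w]
        d.discard(pid)
        if not d:
            del self.directed[w]
        s = self.sig[rep]
        s.discard(pid)
        if len(s) < 2:
            self.deficit += 1
            if len(s) == 1:  # class needs placements again
                self._prefix_delta(rep, +1)
        if not s:
            del self.sig[rep]
        # rep still on pid only if another window of pid maps to it -- ruled
        # out by (1)/(2), so drop unconditionally.
        self.probe_classes[pid].discard(rep)

    def needed_directed(self) -> list[str]:
        """Directed k-mers of classes with probe-support < 2.

        Ordered by descending remaining ambiguity (support 0 before
        support 1), then lexicographically, matching the completion
        heuristic's motif priority.
        """
        out = []
        for rep_motif in _all_reps(self.k):
            s = self.support(rep_motif)
            if s < 2:
                out.append((s, rep_motif))
        out.sort()
        directed = []
        for _, rep_motif in out:
            directed.append(rep_motif)
            rc = reverse_complement(rep_motif)
            if rc != rep_motif:
                directed.append(rc)
        return directed


_REP_CACHE: dict[int, list[str]] = {}


def _all_reps(k: int) -> list[str]:
    if k not in _REP_CACHE:
        _REP_CACHE[k] = sorted(m.representative for m in enumerate_motifs(k))
    return _REP_CACHE[k]


# ---------------------------------------------------------------------------
# Masterstrand construction (backtracking, nucleotide-by-nucleotide)
# ---------------------------------------------------------------------------


def _partitionable(r: int, lo: int, hi: int) -> bool:
    """Can a stretch of r bases be split into segments of length lo..hi?"""
    if r == 0:
        return True
    if r < lo:
        return False
    return -(-r // hi) <= r // lo  # ceil(r/hi) <= floor(r/lo)


_CUT = "__CUT__"


def build_masterstrand(
    books: _Books,
    config: DesignConfig,
    rng: random.Random,
    ms_index: int,
) -> tuple[Masterstrand, list[str]]:
    """Grow one masterstrand of the configured target length.

    Elongation is greedy-guided backtracking: bases completing a window
    whose motif class still needs probe placements are preferred (fixed
    A<C<G<T tie-break); when no such base passes the constraint checks a
    cut-mark is placed (if the open segment is long enough and the
    remaining strand stays partitionable into valid segments), otherwise a
    neutral base is taken; a dead end backtracks. Returns the strand and
    the ordered probe ids assigned to its segments.
    """
    k = config.k
    lo, hi = config.min_probe_len, config.max_probe_len
    target = config.masterstrand_target_len
    seq: list[str] = []
    cut_marks: list[int] = []
    seg_ids: list[str] = []
    seg_no = 0
    pid = f"MS{ms_index}_{seg_no:03d}"
    books.open_probe(pid)
    seg_ids.append(pid)
    seg_start = 0
    steps = 0
    # decision stack: (kind, alternatives, next_index, payload)
    stack: list[list] = []

    def seed_candidates() -> list[str]:
        needed = books.needed_directed()
        cands = [w for w in needed if books.window_ok(pid, w)]
        if not cands:
            # all classes placed twice (or blocked): any clean window will do
            for tup in itertools.product(DNA_BASES, repeat=k):
                w = "".join(tup)
                if books.window_ok(pid, w):
                    cands.append(w)
                    if len(cands) >= 8:
                        break
        cands = cands[:64]
        rng.shuffle(cands)  # lets different seeds explore different strands
        return cands

    def elongation_candidates() -> list[str]:
        seg_len = len(seq) - seg_start
        ctx = "".join(seq[-(k - 1) :]) if k > 1 else ""
        gains, bridges, neutrals = [], [], []
        if seg_len < hi:
            for b in DNA_BASES:
                w = ctx + b
                if not books.window_ok(pid, w):
                    continue
                rep = canonical_representative(w)
                if books.support(rep) < 2:
                    gains.append(w)
                elif books.needed_prefix.get(w[1:], 0) > 0:
                    bridges.append(w)  # neutral now, adjacent to needed space
                else:
                    neutrals.append(w)
        # prefer the gain whose successor context points back into needed
        # sequence space: keeps gain runs long (base order breaks ties)
        gains.sort(key=lambda w: -books.needed_prefix.get(w[1:], 0))
        remaining = target - len(seq)
        can_cut = seg_len >= lo and _partitionable(remaining, lo, hi)
        must_cut = can_cut and not any(
            _partitionable(remaining - d, lo, hi) for d in range(1, hi - seg_len + 1)
        )
        if must_cut:
            return [_CUT]
        cands = gains + bridges
        if can_cut:
            cands.append(_CUT)
        cands.extend(neutrals)
        return cands

    def apply(choice: str) -> None:
        nonlocal seg_start, seg_no, pid
        if choice == _CUT:
            cut_marks.append(len(seq))
            seg_start = len(seq)
            seg_no += 1
            pid = f"MS{ms_index}_{seg_no:03d}"
            books.open_probe(pid)
            seg_ids.append(pid)
        elif len(choice) == k and len(seq) == seg_start:  # segment seed
            seq.extend(choice)
            books.add_window(pid, choice)
        else:
            seq.append(choice[-1])
            books.add_window(pid, choice)

    def undo(choice: str) -> None:
        nonlocal seg_start, seg_no, pid
        if choice == _CUT:
            books.drop_probe(pid)
            seg_ids.pop()
            seg_no -= 1
            pid = seg_ids[-1]
            cut_marks.pop()
            seg_start = cut_marks[-1] if cut_marks else 0
        elif len(seq) - seg_start == k and len(choice) == k:
            books.remove_window(pid, choice)
            del seq[-k:]
        else:
            books.remove_window(pid, choice)
            seq.pop()

    while len(seq) < target:
        at_seg_start = len(seq) == seg_start
        cands = seed_candidates() if at_seg_start else elongation_candidates()
        frame = [cands, 0]
        # descend into first viable candidate, else backtrack
        while True:
            if frame[1] < len(frame[0]):
                choice = frame[0][frame[1]]
                frame[1] += 1
                apply(choice)
                stack.append([frame, choice])
                break
            # exhausted: pop a previous decision
            steps += 1
            if steps > config.max_backtrack_steps or not stack:
                raise DesignError(
                    f"masterstrand {ms_index}: search exhausted after {steps} "
                    "backtrack steps; reseed or relax the configuration"
                )
            prev_frame, prev_choice = stack.pop()
            undo(prev_choice)
            frame = prev_frame

    assert len(seq) > seg_start, "strand may not end on an open cut"
    return Masterstrand(sequence="".join(seq), cut_marks=cut_marks), seg_ids


# ---------------------------------------------------------------------------
# Ambiguity analysis and greedy completion
# ---------------------------------------------------------------------------


@dataclass
class AmbiguityReport:
    """Motifs whose encoding does not yet identify them uniquely."""

    missing: list[str]  # class reps with probe support < 2
    collisions: list[list[str]]  # groups sharing an identical probe set
    dominated: list[tuple[str, str]]  # (m1, m2) with sig(m1) a strict subset
    pair_violations: list[tuple]

    @property
    def empty(self) -> bool:
        return not (
            self.missing or self.collisions or self.dominated or self.pair_violations
        )


def find_ambiguities(library: ProbeLibrary, config: DesignConfig) -> AmbiguityReport:
    sig = library.signature_index()
    missing = sorted(
        rep for rep in _all_reps(config.k) if len(sig.get(rep, ())) < 2
    )
    by_set: dict[frozenset, list[str]] = {}
    for rep, s in sig.items():
        by_set.setdefault(s, []).append(rep)
    collisions = sorted(sorted(g) for g in by_set.values() if len(g) > 1)
    dominated = []
    reps = sorted(sig)
    # subset detection via shared probes (signatures are small sets)
    probe_classes: dict[str, list[str]] = {}
    for rep, s in sig.items():
        for pidn in s:
            probe_classes.setdefault(pidn, []).append(rep)
    seen_pairs = set()
    for r1 in reps:
        s1 = sig[r1]
        candidates = set()
        for pidn in s1:
            candidates.update(probe_classes[pidn])
        for r2 in candidates:
            if r2 == r1:
                continue
            s2 = sig[r2]
            if s2 < s1 and (r2, r1) not in seen_pairs:
                seen_pairs.add((r2, r1))
                dominated.append((r2, r1))
    dominated.sort()
    return AmbiguityReport(
        missing=missing,
        collisions=collisions,
        dominated=dominated,
        pair_violations=check_pair_rule(library),
    )


def _extension_candidates(
    books: _Books, seq: str, config: DesignConfig, rng: random.Random
) -> list[str]:
    """Candidate extensions of a completion probe, best first.

    Needed directed k-mers with the longest suffix overlap come first
    (shorter appended text packs more motifs per base); overlap ties break
    towards classes with the higher remaining ambiguity (support 0 before
    support 1), then towards candidates whose own suffix is the prefix of
    further needed motifs (keeps the probe packable), then
    lexicographically. Below the 11 bp length floor, single neutral filler
    bases are offered last so a poisoned tail can be re-anchored.
    """
    k = config.k
    needed = books.needed_directed()
    chain: dict[str, int] = {}
    for w in needed:
        p = w[: k - 1]
        chain[p] = chain.get(p, 0) + 1
    out: list[str] = []
    max_overlap = min(k - 1, len(seq))
    for overlap in range(max_overlap, -1, -1):
        if len(seq) + k - overlap > config.max_probe_len:
            continue
        tail = seq[len(seq) - overlap :] if overlap else ""
        tier = [w for w in needed if w.startswith(tail)]
        tier.sort(
            key=lambda w: (
                books.support(canonical_representative(w)),
                -chain.get(w[1:], 0),
                w,
            )
        )
        out.extend(w[overlap:] for w in tier[:12])
    if len(seq) < config.min_completion_probe_len:
        bases = list(DNA_BASES)
        rng.shuffle(bases)
        out.extend(bases)
    return out


def _apply_extension(
    books: _Books, pid: str, seq: str, ext: str, k: int
) -> list[str] | None:
    """Add the windows created by appending ``ext``; None (and no state
    change) if any window fails the constraint checks."""
    new_seq = seq + ext
    added: list[str] = []
    for i in range(len(seq) + 1, len(new_seq) + 1):
        if i < k:
            continue
        win = new_seq[i - k : i]
        if not books.window_ok(pid, win):
            for w in reversed(added):
                books.remove_window(pid, w)
            return None
        books.add_window(pid, win)
        added.append(win)
    return added


def _build_completion_probe(
    books: _Books, pid: str, config: DesignConfig, rng: random.Random
) -> str | None:
    """One completion probe, by depth-first search over extensions.

    Greedily packs needed motifs; when a tail wedges (every extension
    violates a constraint) the search backs out of the last extension and
    tries the next candidate. The probe is finalized once no needed motif
    fits and the 11 bp floor is reached.
    """
    books.open_probe(pid)
    seq = ""
    stack: list[tuple[str, list[str], int, list[str]]] = []
    cands = _extension_candidates(books, seq, config, rng)
    idx = 0
    budget = 500
    while True:
        if idx < len(cands):
            ext = cands[idx]
            idx += 1
            added = _apply_extension(books, pid, seq, ext, config.k)
            if added is None:
                continue
            stack.append((seq, cands, idx, added))
            seq = seq + ext
            cands = _extension_candidates(books, seq, config, rng)
            idx = 0
            continue
        # no extension fits: finalize if legal, else backtrack
        if config.min_completion_probe_len <= len(seq) <= config.max_probe_len:
            return seq
        budget -= 1
        if budget <= 0 or not stack:
            books.abort_probe(pid)
            return None
        seq, cands, idx, added = stack.pop()
        for w in reversed(added):
            books.remove_window(pid, w)


def greedy_complete(
    books: _Books,
    probes: list[LibraryProbe],
    config: DesignConfig,
    rng: random.Random,
) -> list[LibraryProbe]:
    """Append completion probes until every motif class has support >= 2.

    Windows are only accepted if they place a still-needed motif (or are
    neutral filler needed to reach the 11 bp minimum) and keep the
    signature family subset-free, so finishing the loop certifies an
    unambiguous library. Raises :class:`DesignError` when the well budget
    is exhausted or a probe stops reducing ambiguity.
    """
    n_comp = 0
    while books.deficit > 0:
        if len(probes) >= config.max_library_probes:
            raise DesignError(
                f"well budget exhausted: {len(probes)} library probes + "
                f"{config.n_control_wells} controls exceed {config.well_budget} wells"
            )
        n_comp += 1
        pid = f"C{n_comp:03d}"
        before = books.deficit
        seq = None
        for _ in range(5):  # dead ends are rare; retry with fresh filler order
            seq = _build_completion_probe(books, pid, config, rng)
            if seq is not None:
                break
        if seq is None:
            raise DesignError(f"could not build completion probe {pid}")
        if books.deficit >= before:
            books.abort_probe(pid)
            raise DesignError(
                "completion made no progress; remaining motifs are blocked"
            )
        probes.append(LibraryProbe(pid, seq, "completion"))
    return probes


# ---------------------------------------------------------------------------
# Orchestration and validation
# ---------------------------------------------------------------------------


def design_library(config: DesignConfig | None = None) -> ProbeLibrary:
    """Run the full two-step design: masterstrands, cutting, completion.

    Deterministic for a given config seed. Restarts with a derived seed
    (up to ``max_restarts`` times) if the backtracking search dies.
    """
    config = config or DesignConfig()
    last_err: Exception | None = None
    for attempt in range(config.max_restarts):
        rng = random.Random((config.seed * 1_000_003 + attempt) % 2**31)
        books = _Books(config.k)
        probes: list[LibraryProbe] = []
        strands: list[Masterstrand] = []
        try:
            for i in range(1, config.n_masterstrands + 1):
                ms, seg_ids = build_masterstrand(books, config, rng, i)
                strands.append(ms)
                for seg_pid, region in zip(seg_ids, cut_masterstrand(ms)):
                    probes.append(
                        LibraryProbe(seg_pid, region, f"masterstrand_{i}")
                    )
            probes = greedy_complete(books, probes, config, rng)
        except DesignError as err:
            last_err = err
            continue
        return ProbeLibrary(probes=probes, k=config.k, masterstrands=strands)
    raise DesignError(f"design failed after {config.max_restarts} attempts: {last_err}")


@dataclass
class ValidationReport:
    """Itemized pass/fail of every library constraint."""

    segment_violations: dict[str, list[tuple]]
    pair_violations: list[tuple]
    length_violations: list[tuple[str, int]]
    uncovered: list[str]
    under_supported: list[str]
    collisions: list[list[str]]
    dominated: list[tuple[str, str]]
    n_probes: int = 0
    n_wells_needed: int = 0
    well_budget: int = 384
    passed: bool = False

    def failures(self) -> list[str]:
        out = []
        for pid, v in self.segment_violations.items():
            out.append(f"probe {pid}: per-probe constraint violations {v}")
        if self.pair_violations:
            out.append(f"pair rule (3) violated: {self.pair_violations[:5]}...")
        for pid, n in self.length_violations:
            out.append(f"probe {pid}: variable region of {n} bp out of bounds")
        if self.uncovered:
            out.append(f"{len(self.uncovered)} motif classes absent from library")
        if self.under_supported:
            out.append(
                f"{len(self.under_supported)} motif classes on fewer than 2 probes"
            )
        if self.collisions:
            out.append(f"{len(self.collisions)} signature collisions")
        if self.dominated:
            out.append(f"{len(self.dominated)} dominated signatures")
        if self.n_wells_needed > self.well_budget:
            out.append(
                f"{self.n_wells_needed} wells needed exceeds budget {self.well_budget}"
            )
        return out


def validate_library(
    library: ProbeLibrary, config: DesignConfig | None = None
) -> ValidationReport:
    """Independent full-scan check of a designed or loaded library."""
    config = config or DesignConfig()
    k = config.k
    seg_viol = {}
    len_viol = []
    for p in library.probes:
        v = check_segment(p.variable_region, k)
        if v:
            seg_viol[p.probe_id] = v
        n = len(p.variable_region)
        lo = (
            config.min_completion_probe_len
            if p.source == "completion"
            else config.min_probe_len
        )
        if not lo <= n <= config.max_probe_len:
            len_viol.append((p.probe_id, n))
    amb = find_ambiguities(library, config)
    sig = library.signature_index()
    uncovered = sorted(r for r in _all_reps(k) if r not in sig)
    n_wells = len(library.probes) + config.n_control_wells
    report = ValidationReport(
        segment_violations=seg_viol,
        pair_violations=amb.pair_violations,
        length_violations=len_viol,
        uncovered=uncovered,
        under_supported=amb.missing,
        collisions=amb.collisions,
        dominated=amb.dominated,
        n_probes=len(library.probes),
        n_wells_needed=n_wells,
        well_budget=config.well_budget,
    )
    report.passed = not report.failures()
    return report
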