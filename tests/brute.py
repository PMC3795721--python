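"""Independent brute-force oracles, written from the constraint definitions
alone (Biopython for sequence arithmetic; no dpiscreen internals)."""

import itertools
import math

from Bio.Seq import Seq


def rc(s: str) -> str:
    return str(Seq(s).reverse_complement())


def canon(s: str) -> str:
    return min(s, rc(s))


def windows(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def all_kmers(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


def brute_validate(
    probes: dict[str, str],
    k: int,
    min_len: int,
    max_len: int,
    min_completion_len: int,
    completion_ids: set[str],
    max_probes: int,
) -> list[str]:
    """Every library constraint checked the slow, obvious way.

    ``probes`` maps probe id -> variable region. Returns failure strings.
    """
    failures = []
    # per-probe constraints (1), (2), (4) and length bounds (5)/(6)
    for pid, seq in probes.items():
        lo = min_completion_len if pid in completion_ids else min_len
        if not lo <= len(seq) <= max_len:
            failures.append(f"length:{pid}")
        wins = windows(seq, k)
        if len(wins) != len(set(wins)):
            failures.append(f"dup-kmer:{pid}")
        for w in set(wins):
            if rc(w) != w and rc(w) in wins:
                failures.append(f"rc-pair-on-probe:{pid}")
                break
        pals = [w for w in set(wins) if rc(w) == w]
        if len(pals) > 1:
            failures.append(f"two-palindromes:{pid}")
    # global pair rule (3)
    ids = sorted(probes)
    for pa, pb in itertools.product(ids, ids):
        wa, wb = set(windows(probes[pa], k)), set(windows(probes[pb], k))
        for m1, m2 in itertools.combinations(sorted(wa), 2):
            if rc(m1) == m1 or rc(m2) == m2:
                continue
            if rc(m1) in wb and rc(m2) in wb:
                failures.append(f"pair-rule:{pa}/{pb}")
                break
    # coverage (a): every directed k-mer on some strand of some probe
    seen = set()
    for seq in probes.values():
        for w in windows(seq, k):
            seen.add(w)
            seen.add(rc(w))
    missing = set(all_kmers(k)) - seen
    if missing:
        failures.append(f"coverage:{len(missing)} missing")
    # support >= 2 and unique, subset-free signatures
    sig = {}
    for pid, seq in probes.items():
        for w in windows(seq, k):
            sig.setdefault(canon(w), set()).add(pid)
    for m, s in sig.items():
        if len(s) < 2:
            failures.append(f"support:{m}")
    reps = sorted(sig)
    for m1, m2 in itertools.combinations(reps, 2):
        if sig[m1] == sig[m2]:
            failures.append(f"collision:{m1}/{m2}")
        elif sig[m1] < sig[m2] or sig[m2] < sig[m1]:
            failures.append(f"dominated:{m1}/{m2}")
    if len(probes) > max_probes:
        failures.append("well-budget")
    return failures


def brute_hypergeom_tail(n_total: int, k_lib: int, n_drawn: int, k_obs: int) -> float:
    """P(X >= k_obs) for a hypergeometric draw, by direct summation."""
    total = 0.0
    for j in range(k_obs, min(k_lib, n_drawn) + 1):
        total += (
            math.comb(k_lib, j)
            * math.comb(n_total - k_lib, n_drawn - j)
            / math.comb(n_total, n_drawn)
        )
    return min(total, 1.0)
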