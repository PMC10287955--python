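"""Independent brute-force oracles used to check the package implementations.

Everything here is written naively (O(n*m) substring loops, explicit
recounts) and must stay independent of the code paths it verifies.
"""

from typing import List, Tuple

STABILIZING = ("UUUUU", "UUGCAUGG", "CCUUACAC")
DESTABILIZING = ("AUUUU", "CCUC", "CUGC", "UAAGUUAU", "UAACUUAU", "GUAAAUAG")


def naive_occurrences(s: str, motif: str) -> List[Tuple[int, int]]:
    """All (possibly overlapping) exact occurrences of `motif` in `s`."""
    return [
        (i, i + len(motif))
        for i in range(len(s) - len(motif) + 1)
        if s[i:i + len(motif)] == motif
    ]


def naive_u_runs(s: str, min_len: int = 5) -> List[Tuple[int, int]]:
    """Maximal runs of U with length >= min_len."""
    runs = []
    i = 0
    while i < len(s):
        if s[i] == "U":
            j = i
            while j < len(s) and s[j] == "U":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def naive_stabilizing_candidates(s: str) -> List[Tuple[str, int, int]]:
    """All stabilizing element occurrences under the default catalog."""
    out = [("UUUUU", i, j) for i, j in naive_u_runs(s)]
    for motif in ("UUGCAUGG", "CCUUACAC"):
        out += [(motif, i, j) for i, j in naive_occurrences(s, motif)]
    return sorted(out, key=lambda x: x[1])


def naive_destabilizing_candidates(s: str) -> List[Tuple[str, int, int]]:
    """Destabilizing occurrences; AUUUU only when the U-run is exactly 4."""
    out = []
    for motif in DESTABILIZING:
        for i, j in naive_occurrences(s, motif):
            if motif == "AUUUU" and j < len(s) and s[j] == "U":
                continue
            out.append((motif, i, j))
    return sorted(out, key=lambda x: x[1])


def count_stabilizing(s: str) -> int:
    return len(naive_stabilizing_candidates(s))
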