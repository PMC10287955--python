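"""Locate stabilizing and destabilizing ARE motifs in 3'UTR sequences.

Matching semantics
------------------
* Every maximal run of >= 5 consecutive U is a single stabilizing hit of
  motif class ``UUUUU`` spanning the whole run (one stabilizing element per
  contiguous poly-U tract).
* The other stabilizing motifs (``UUGCAUGG``, ``CCUUACAC``) and all
  destabilizing motifs are matched as exact substrings, except ``AUUUU``:
  it is reported only when the U-run following the A is exactly 4 long;
  longer runs are stabilizing poly-U hits instead.
* On residue overlap between a stabilizing and a destabilizing candidate
  the stabilizing hit wins; among remaining same-class overlaps,
  leftmost-then-longest wins.  Reported hits never share a residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

from .errors import EmptyInputError, ValidationError
from .seqcore import NucleotideSequence

DEFAULT_STABILIZING: Tuple[str, ...] = ("UUUUU", "UUGCAUGG", "CCUUACAC")
DEFAULT_DESTABILIZING: Tuple[str, ...] = (
    "AUUUU",
    "CCUC",
    "CUGC",
    "UAAGUUAU",
    "UAACUUAU",
    "GUAAAUAG",
)
DEFAULT_REPLACEMENT_MAP: Dict[str, str] = {
    "UUUUU": "CCUC",
    "UUGCAUGG": "CUGC",
    "CCUUACAC": "UAAGUUAU",
}

_RNA = frozenset("ACGU")


class MotifClass(str, Enum):
    STABILIZING = "stabilizing"
    DESTABILIZING = "destabilizing"


def _check_motif(m: str, role: str) -> str:
    if not m:
        raise ValidationError(f"empty {role} motif")
    if set(m) - _RNA:
        raise ValidationError(f"{role} motif {m!r} has non-RNA residues")
    return m


@dataclass(frozen=True)
class MotifCatalog:
    """The stabilizing/destabilizing motif sets and their replacement mapping."""

    stabilizing: Tuple[str, ...] = DEFAULT_STABILIZING
    destabilizing: Tuple[str, ...] = DEFAULT_DESTABILIZING
    replacement_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REPLACEMENT_MAP)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "stabilizing", tuple(self.stabilizing))
        object.__setattr__(self, "destabilizing", tuple(self.destabilizing))
        object.__setattr__(self, "replacement_map", dict(self.replacement_map))
        for m in self.stabilizing:
            _check_motif(m, "stabilizing")
        for m in self.destabilizing:
            _check_motif(m, "destabilizing")
        for k, v in self.replacement_map.items():
            if k not in self.stabilizing:
                raise ValidationError(
                    f"replacement key {k!r} not in stabilizing set"
                )
            if v not in self.destabilizing:
                raise ValidationError(
                    f"replacement value {v!r} not in destabilizing set"
                )

    @classmethod
    def default(cls) -> "MotifCatalog":
        return cls()

    @classmethod
    def from_config(cls, path: Union[str, Path]) -> "MotifCatalog":
        """Build a catalog from a flat key-value config file.

        Recognized keys: ``stabilizing`` / ``destabilizing`` (comma-separated
        motif lists) and ``replace.<MOTIF> = <MOTIF>`` entries.  Motifs may be
        written in DNA (T is mapped to U).  Unknown keys are rejected.
        """
        stab = list(DEFAULT_STABILIZING)
        destab = list(DEFAULT_DESTABILIZING)
        repl = dict(DEFAULT_REPLACEMENT_MAP)
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip().upper().replace("T", "U")
            if key == "stabilizing":
                stab = [v.strip() for v in value.split(",") if v.strip()]
            elif key == "destabilizing":
                destab = [v.strip() for v in value.split(",") if v.strip()]
            elif key.startswith("replace."):
                repl[key[len("replace."):].upper().replace("T", "U")] = value
            else:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
        repl = {k: v for k, v in repl.items() if k in stab}
        return cls(tuple(stab), tuple(destab), repl)


@dataclass(frozen=True)
class MotifHit:
    """A located motif occurrence (0-based, half-open coordinates)."""

    motif: str
    clazz: MotifClass
    start: int
    end: int
    matched_text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad hit interval [{self.start}, {self.end})")
        if len(self.matched_text) != self.end - self.start:
            raise ValidationError("matched_text length disagrees with interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "MotifHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class StabilityProfile:
    """Summary counts of a scan over one sequence."""

    sequence_id: str
    hits: Tuple[MotifHit, ...]
    n_stabilizing: int
    n_destabilizing: int
    net_score: int
    density_per_kb: float


def _u_runs(s: str, min_len: int) -> List[Tuple[int, int]]:
    runs = []
    i = 0
    n = len(s)
    while i < n:
        if s[i] == "U":
            j = i
            while j < n and s[j] == "U":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _exact_occurrences(s: str, motif: str) -> List[int]:
    out = []
    start = s.find(motif)
    while start != -1:
        out.append(start)
        start = s.find(motif, start + 1)
    return out


def _is_polyu_motif(m: str) -> bool:
    return set(m) == {"U"}


def _is_a_polyu_motif(m: str) -> bool:
    # 'A' followed by U's, e.g. AUUUU: subject to the exact-run-length rule.
    return len(m) >= 2 and m[0] == "A" and set(m[1:]) == {"U"}


def _candidates(s: str, catalog: MotifCatalog) -> Tuple[List[MotifHit], List[MotifHit]]:
    stab: List[MotifHit] = []
    for m in catalog.stabilizing:
        if _is_polyu_motif(m):
            for i, j in _u_runs(s, len(m)):
                stab.append(MotifHit(m, MotifClass.STABILIZING, i, j, s[i:j]))
        else:
            for i in _exact_occurrences(s, m):
                stab.append(
                    MotifHit(m, MotifClass.STABILIZING, i, i + len(m), m)
                )
    destab: List[MotifHit] = []
    for m in catalog.destabilizing:
        if _is_a_polyu_motif(m):
            run = len(m) - 1
            for i in _exact_occurrences(s, m):
                after = i + len(m)
                if after < len(s) and s[after] == "U":
                    continue  # U-run longer than the motif: poly-U territory
                destab.append(
                    MotifHit(m, MotifClass.DESTABILIZING, i, after, m)
                )
        else:
            for i in _exact_occurrences(s, m):
                destab.append(
                    MotifHit(m, MotifClass.DESTABILIZING, i, i + len(m), m)
                )
    return stab, destab


def _greedy_select(cands: List[MotifHit], occupied: List[MotifHit]) -> List[MotifHit]:
    """Leftmost-then-longest non-overlapping selection avoiding `occupied`."""
    chosen: List[MotifHit] = []
    for c in sorted(cands, key=lambda h: (h.start, -h.length)):
        if any(c.overlaps(o) for o in occupied):
            continue
        if any(c.overlaps(o) for o in chosen):
            continue
        chosen.append(c)
    return chosen


def scan_motifs(
    seq: NucleotideSequence, catalog: Union[MotifCatalog, None] = None
) -> List[MotifHit]:
    """Scan a normalized sequence for catalog motifs.

    Returns hits sorted by start, mutually non-overlapping, following the
    priority rules documented in the module docstring.  Deterministic.
    """
    if catalog is None:
        catalog = MotifCatalog.default()
    s = seq.residues
    if not s:
        raise EmptyInputError("cannot scan an empty sequence")
    stab_cands, destab_cands = _candidates(s, catalog)
    stab_hits = _greedy_select(stab_cands, [])
    destab_hits = _greedy_select(destab_cands, stab_hits)
    return sorted(stab_hits + destab_hits, key=lambda h: h.start)


def stability_profile(
    seq: NucleotideSequence, hits: Sequence[MotifHit]
) -> StabilityProfile:
    """Tally hits into a per-sequence stability profile."""
    for h in hits:
        if h.end > len(seq.residues):
            raise ValidationError(
                f"hit [{h.start}, {h.end}) out of bounds for {seq.id!r}"
            )
        if seq.residues[h.start:h.end] != h.matched_text:
            raise ValidationError(
                f"hit at [{h.start}, {h.end}) does not match sequence {seq.id!r}"
            )
    n_stab = sum(1 for h in hits if h.clazz is MotifClass.STABILIZING)
    n_destab = sum(1 for h in hits if h.clazz is MotifClass.DESTABILIZING)
    return StabilityProfile(
        sequence_id=seq.id,
        hits=tuple(sorted(hits, key=lambda h: h.start)),
        n_stabilizing=n_stab,
        n_destabilizing=n_destab,
        net_score=n_stab - n_destab,
        density_per_kb=1000.0 * n_stab / len(seq.residues),
    )


def hits_to_bed(seq_id: str, hits: Sequence[MotifHit]) -> str:
    """Render hits as BED6 lines (name = motif:class, score 0, strand +)."""
    lines = [
        f"{seq_id}\t{h.start}\t{h.end}\t{h.motif}:{h.clazz.value}\t0\t+"
        for h in sorted(hits, key=lambda h: h.start)
    ]
    return "".join(line + "\n" for line in lines)
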