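"""Assemble the synthetic gBlock and run synthesis/cloning sanity checks.

Part order is fixed: BstBI site, 5' poly-A, promoter, insert, 3' poly-A,
BamHI site.  Output is DNA; coordinates are 0-based half-open over the full
construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple, Union

from .errors import ValidationError
from .seqcore import NucleotideSequence, to_dna

BSTBI_SITE = "TTCGAA"
BAMHI_SITE = "GGATCC"

PART_ORDER = (
    "bstb1_site",
    "polya_5p",
    "promoter",
    "insert",
    "polya_3p",
    "bamh1_site",
)

DEFAULT_POLYA_LEN = 30
DEFAULT_HOMOPOLYMER_LIMIT = 60


@dataclass(frozen=True)
class Part:
    name: str
    sequence: str  # DNA
    start: int
    end: int


@dataclass(frozen=True)
class Issue:
    """A validation finding (not an exception)."""

    kind: str  # "internal_site" | "non_acgt" | "homopolymer"
    part: str
    offset: int  # offset within the named part
    detail: str


@dataclass(frozen=True)
class ConstructSpec:
    parts: Tuple[Part, ...]
    full_sequence: str
    issues: Tuple[Issue, ...]

    def part(self, name: str) -> Part:
        for p in self.parts:
            if p.name == name:
                return p
        raise KeyError(name)

    def parts_tsv(self) -> str:
        lines = ["name\tstart\tend\tlength"]
        lines += [f"{p.name}\t{p.start}\t{p.end}\t{p.end - p.start}" for p in self.parts]
        return "".join(line + "\n" for line in lines)


def assemble_gblock(
    insert: NucleotideSequence,
    promoter: NucleotideSequence,
    polya_5p_len: int = DEFAULT_POLYA_LEN,
    polya_3p_len: int = DEFAULT_POLYA_LEN,
    homopolymer_limit: int = DEFAULT_HOMOPOLYMER_LIMIT,
) -> ConstructSpec:
    """Concatenate the six parts in fixed order and validate the result.

    The insert and promoter are converted RNA -> DNA; poly-A lengths must be
    >= 1 (an empty promoter or insert is rejected upstream by the sequence
    type).
    """
    if polya_5p_len < 1 or polya_3p_len < 1:
        raise ValidationError("poly-A lengths must be >= 1")
    segments = (
        ("bstb1_site", BSTBI_SITE),
        ("polya_5p", "A" * polya_5p_len),
        ("promoter", to_dna(promoter)),
        ("insert", to_dna(insert)),
        ("polya_3p", "A" * polya_3p_len),
        ("bamh1_site", BAMHI_SITE),
    )
    parts: List[Part] = []
    pos = 0
    for name, seq in segments:
        parts.append(Part(name=name, sequence=seq, start=pos, end=pos + len(seq)))
        pos += len(seq)
    full = "".join(seq for _, seq in segments)
    spec = ConstructSpec(parts=tuple(parts), full_sequence=full, issues=())
    issues = validate_construct(spec, homopolymer_limit=homopolymer_limit)
    return ConstructSpec(parts=tuple(parts), full_sequence=full, issues=tuple(issues))


def _part_at(parts: Tuple[Part, ...], offset: int) -> Part:
    for p in parts:
        if p.start <= offset < p.end:
            return p
    return parts[-1]


def _homopolymer_runs(s: str) -> List[Tuple[int, int, str]]:
    runs = []
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        runs.append((i, j, s[i]))
        i = j
    return runs


def validate_construct(
    spec: ConstructSpec,
    homopolymer_limit: int = DEFAULT_HOMOPOLYMER_LIMIT,
) -> List[Issue]:
    """Flag cloning/synthesis problems; an empty list means pass.

    Checks: (a) BstBI/BamHI recognition sequences anywhere outside the
    designated terminal parts (they would be cut during cloning), (b) any
    non-ACGT character, (c) homopolymer runs whose length outside the
    declared poly-A parts exceeds `homopolymer_limit`.
    """
    full = spec.full_sequence
    issues: List[Issue] = []
    terminal = {
        "bstb1_site": (spec.part("bstb1_site").start, spec.part("bstb1_site").end),
        "bamh1_site": (spec.part("bamh1_site").start, spec.part("bamh1_site").end),
    }
    for site, enzyme in ((BSTBI_SITE, "BstBI"), (BAMHI_SITE, "BamHI")):
        start = full.find(site)
        while start != -1:
            span = (start, start + len(site))
            if span not in terminal.values():
                part = _part_at(spec.parts, start)
                issues.append(
                    Issue(
                        kind="internal_site",
                        part=part.name,
                        offset=start - part.start,
                        detail=f"internal {enzyme} site {site} at construct "
                        f"offset {start}",
                    )
                )
            start = full.find(site, start + 1)
    for i, ch in enumerate(full):
        if ch not in "ACGT":
            part = _part_at(spec.parts, i)
            issues.append(
                Issue(
                    kind="non_acgt",
                    part=part.name,
                    offset=i - part.start,
                    detail=f"non-ACGT character {ch!r} at construct offset {i}",
                )
            )
    polya_spans = [
        (p.start, p.end) for p in spec.parts if p.name in ("polya_5p", "polya_3p")
    ]
    for i, j, base in _homopolymer_runs(full):
        # declared poly-A residues are expected; only the portion of a run
        # outside those spans counts against the synthesis limit
        inside = sum(
            max(0, min(j, hi) - max(i, lo)) for lo, hi in polya_spans
        )
        if (j - i) - inside <= homopolymer_limit:
            continue
        part = _part_at(spec.parts, i)
        issues.append(
            Issue(
                kind="homopolymer",
                part=part.name,
                offset=i - part.start,
                detail=f"homopolymer run of {j - i} {base} exceeds synthesis "
                f"limit {homopolymer_limit}",
            )
        )
    return issues
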