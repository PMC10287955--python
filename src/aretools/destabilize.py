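"""Plan and apply the stabilizing -> destabilizing rewrite.

A rewrite plan carries one motif-swap edit per stabilizing hit (replacement
taken from the catalog's replacement map; a maximal poly-U run of any length
>= 5 maps to a single replacement) plus optional single-residue edits whose
positions are user-supplied.  Swaps are applied right-to-left so earlier
coordinates stay valid; residue edits are applied after the swaps, on the
rewritten sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

from .are_scan import MotifCatalog, MotifClass, scan_motifs
from .errors import (
    EditMismatchError,
    NonConvergenceError,
    StalePlanError,
    UnmappedMotifError,
    ValidationError,
)
from .seqcore import NucleotideSequence

DESTABILIZED_SUFFIX = ".desARE"

# Base-change identities of the stem-loop stability edits; positions are
# construct-specific and must be supplied by the user.
RESIDUE_EDIT_PRESET: Tuple[Tuple[str, str, str], ...] = (
    ("M5", "C", "U"),
    ("M6", "U", "C"),
    ("M11", "A", "U"),
)


@dataclass(frozen=True)
class EditOperation:
    """One planned edit in current-sequence coordinates."""

    kind: str  # "motif_swap" | "residue_edit"
    start: int
    end: int
    original: str
    replacement: str
    rule_label: str

    def __post_init__(self) -> None:
        if self.kind not in ("motif_swap", "residue_edit"):
            raise ValidationError(f"unknown edit kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad edit interval [{self.start}, {self.end})")
        if len(self.original) != self.end - self.start:
            raise ValidationError("original length disagrees with interval")


@dataclass(frozen=True)
class ResidueEdit:
    """A single-base substitution at a user-supplied position."""

    label: str
    position: int
    from_base: str
    to_base: str

    def __post_init__(self) -> None:
        for b in (self.from_base, self.to_base):
            if b not in "ACGU":
                raise ValidationError(f"residue edit base {b!r} not in ACGU")
        if self.from_base == self.to_base:
            raise ValidationError(
                f"residue edit {self.label!r}: from and to base are equal"
            )
        if self.position < 0:
            raise ValidationError(f"residue edit {self.label!r}: negative position")


@dataclass(frozen=True)
class RewritePlan:
    """Ordered, non-overlapping edits turning a sequence into its destabilized form."""

    sequence_id: str
    swaps: Tuple[EditOperation, ...]
    residue_edits: Tuple[ResidueEdit, ...] = ()
    catalog: MotifCatalog = field(default_factory=MotifCatalog.default)

    def __post_init__(self) -> None:
        object.__setattr__(self, "swaps", tuple(self.swaps))
        object.__setattr__(self, "residue_edits", tuple(self.residue_edits))
        prev_end = -1
        for op in self.swaps:
            if op.kind != "motif_swap":
                raise ValidationError("plan swaps must be motif_swap edits")
            if op.start < prev_end:
                raise ValidationError("plan swaps overlap or are unsorted")
            prev_end = op.end


@dataclass(frozen=True)
class RewriteRound:
    """Per-round record emitted by :func:`verify_destabilized`."""

    round: int
    n_swaps: int
    length_before: int
    length_after: int


def plan_rewrite(
    seq: NucleotideSequence, catalog: Union[MotifCatalog, None] = None
) -> RewritePlan:
    """Build a rewrite plan with one motif swap per stabilizing hit."""
    if catalog is None:
        catalog = MotifCatalog.default()
    swaps: List[EditOperation] = []
    for hit in scan_motifs(seq, catalog):
        if hit.clazz is not MotifClass.STABILIZING:
            continue
        replacement = catalog.replacement_map.get(hit.motif)
        if replacement is None:
            raise UnmappedMotifError(
                f"stabilizing motif {hit.motif!r} at [{hit.start}, {hit.end}) "
                f"has no replacement-map entry"
            )
        swaps.append(
            EditOperation(
                kind="motif_swap",
                start=hit.start,
                end=hit.end,
                original=hit.matched_text,
                replacement=replacement,
                rule_label=f"{hit.motif}->{replacement}",
            )
        )
    return RewritePlan(sequence_id=seq.id, swaps=tuple(swaps), catalog=catalog)


def apply_rewrite(seq: NucleotideSequence, plan: RewritePlan) -> NucleotideSequence:
    """Apply a plan's motif swaps; residues outside swap intervals are untouched.

    The output id gains a ``.desARE`` suffix (once).  A plan whose recorded
    originals no longer match the sequence raises :class:`StalePlanError`.
    """
    if plan.sequence_id != seq.id:
        raise StalePlanError(
            f"plan was built for {plan.sequence_id!r}, not {seq.id!r}"
        )
    residues = seq.residues
    for op in plan.swaps:
        if residues[op.start:op.end] != op.original:
            raise StalePlanError(
                f"swap {op.rule_label} at [{op.start}, {op.end}): expected "
                f"{op.original!r}, found {residues[op.start:op.end]!r}; "
                f"sequence changed since planning"
            )
    for op in sorted(plan.swaps, key=lambda o: o.start, reverse=True):
        residues = residues[: op.start] + op.replacement + residues[op.end:]
    new_id = seq.id
    if not new_id.endswith(DESTABILIZED_SUFFIX):
        new_id += DESTABILIZED_SUFFIX
    return seq.with_residues(residues, id=new_id)


def apply_residue_edits(
    seq: NucleotideSequence, edits: Sequence[ResidueEdit]
) -> NucleotideSequence:
    """Apply single-base edits; each position must carry the expected base."""
    positions = [e.position for e in edits]
    if len(set(positions)) != len(positions):
        raise ValidationError("duplicate positions in residue edit list")
    residues = list(seq.residues)
    for e in edits:
        if e.position >= len(residues):
            raise ValidationError(
                f"residue edit {e.label!r}: position {e.position} beyond "
                f"sequence length {len(residues)}"
            )
        if residues[e.position] != e.from_base:
            raise EditMismatchError(
                f"residue edit {e.label!r} at {e.position}: expected "
                f"{e.from_base}, found {residues[e.position]}"
            )
        residues[e.position] = e.to_base
    return seq.with_residues("".join(residues))


def verify_destabilized(
    seq: NucleotideSequence,
    catalog: Union[MotifCatalog, None] = None,
    max_rounds: int = 10,
) -> Tuple[NucleotideSequence, List[RewriteRound]]:
    """Iterate plan/apply until the scan finds zero stabilizing hits.

    A swap junction can in principle create a new motif, so rewriting is
    repeated to a fixed point (at most ``max_rounds`` rounds).  Returns the
    final sequence and a per-round report; an already-destabilized input is
    returned unchanged with an empty report.
    """
    if catalog is None:
        catalog = MotifCatalog.default()
    current = seq
    report: List[RewriteRound] = []
    for rnd in range(1, max_rounds + 1):
        plan = plan_rewrite(current, catalog)
        if not plan.swaps:
            return current, report
        before = len(current.residues)
        current = apply_rewrite(current, plan)
        report.append(
            RewriteRound(
                round=rnd,
                n_swaps=len(plan.swaps),
                length_before=before,
                length_after=len(current.residues),
            )
        )
    residual = [
        h for h in scan_motifs(current, catalog)
        if h.clazz is MotifClass.STABILIZING
    ]
    if residual:
        raise NonConvergenceError(
            f"no fixed point after {max_rounds} rounds; residual stabilizing "
            f"hits: {[(h.motif, h.start, h.end) for h in residual]}"
        )
    return current, report
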