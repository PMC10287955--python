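"""Synthetic fixtures: planted-motif UTRs and simulated pulse-chase tables.

The UTR generator draws its background from {A, C, G} by default, so every
U in the sequence comes from a planted motif and the planted records are
airtight ground truth for the scanner.  The pulse-chase simulator emits
paired target/reference Ct rows with multiplicative log-normal noise on
abundance (equivalent to additive Gaussian noise on Ct).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ValidationError
from .kinetics import QpcrMeasurement
from .seqcore import Alphabet, NucleotideSequence

# chase sampling grid used throughout: 0 h, 30 min, 1 h, 3 h, 6 h, 24 h
DEFAULT_CHASE_TIMES_H: Tuple[float, ...] = (0.0, 0.5, 1.0, 3.0, 6.0, 24.0)

_RNA = frozenset("ACGU")


@dataclass(frozen=True)
class PlantedSequence:
    """A generated sequence plus ground-truth planted motif positions."""

    sequence: NucleotideSequence
    planted: Tuple[Tuple[str, int], ...]
    seed: int


def _normalize_motif(motif: str) -> str:
    m = motif.strip().upper().replace("T", "U")
    if not m or set(m) - _RNA:
        raise ValidationError(f"invalid motif {motif!r}")
    return m


def generate_utr(
    length: int,
    plant: Sequence[Tuple[str, Optional[int]]] = (),
    seed: int = 0,
    allow_background_motifs: bool = False,
) -> PlantedSequence:
    """Generate a background sequence with motifs stamped at known positions.

    ``plant`` is a list of (motif, position) pairs; a position of ``None``
    is placed uniformly at random without overlapping other plants.  With
    ``allow_background_motifs=False`` the background is uniform over
    {A, C, G} (no U), so no accidental poly-U or U-containing catalog motif
    can occur; set it to True for a uniform-ACGU stress background.
    """
    if length < 1:
        raise ValidationError("length must be >= 1")
    requests = [(_normalize_motif(m), p) for m, p in plant]
    if sum(len(m) for m, _ in requests) > length:
        raise ValidationError("planted motifs do not fit in the sequence")
    rng = np.random.default_rng(seed)

    placed: List[Tuple[str, int]] = []

    def overlaps(start: int, motif_len: int) -> bool:
        return any(
            start < p + len(m) and p < start + motif_len for m, p in placed
        )

    for m, p in requests:
        if p is not None:
            if p < 0 or p + len(m) > length:
                raise ValidationError(
                    f"motif {m!r} at {p} does not fit in length {length}"
                )
            if overlaps(p, len(m)):
                raise ValidationError(f"motif {m!r} at {p} overlaps another plant")
            placed.append((m, p))
    for m, p in requests:
        if p is None:
            for _ in range(10000):
                cand = int(rng.integers(0, length - len(m) + 1))
                if not overlaps(cand, len(m)):
                    placed.append((m, cand))
                    break
            else:
                raise ValidationError(
                    f"could not place motif {m!r} without overlap"
                )

    background = "ACGU" if allow_background_motifs else "ACG"
    residues = list(rng.choice(list(background), size=length))
    for m, p in placed:
        residues[p:p + len(m)] = list(m)
    seq = NucleotideSequence(
        id=f"synthutr-{seed}",
        residues="".join(residues),
        source_alphabet=Alphabet.RNA,
    )
    return PlantedSequence(
        sequence=seq,
        planted=tuple(sorted(placed, key=lambda x: x[1])),
        seed=seed,
    )


def simulate_pulse_chase(
    half_life_h: float,
    times_h: Sequence[float] = DEFAULT_CHASE_TIMES_H,
    replicates: int = 3,
    noise_cv: float = 0.1,
    ct0: float = 20.0,
    seed: int = 0,
    target: str = "construct",
    reference: str = "ACTB",
) -> List[QpcrMeasurement]:
    """Simulate a labeling pulse-chase qPCR table for a decaying transcript.

    True abundance is A(t) = 2^(-t / half_life).  Each replicate observes
    A(t) times a LogNormal(0, sigma) factor with sigma = sqrt(ln(1 + cv^2)),
    emitted as a target Ct of ``ct0 - log2(observed)`` paired with a constant
    reference Ct of ``ct0``.  Deterministic given `seed`.
    """
    if half_life_h <= 0:
        raise ValidationError("half-life must be positive")
    if not times_h:
        raise ValidationError("need at least one chase time")
    if noise_cv < 0:
        raise ValidationError("noise CV must be >= 0")
    if replicates < 1:
        raise ValidationError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    out: List[QpcrMeasurement] = []
    for t in times_h:
        true_abundance = 2.0 ** (-t / half_life_h)
        for r in range(1, replicates + 1):
            factor = rng.lognormal(0.0, sigma) if sigma > 0 else 1.0
            observed = true_abundance * factor
            sample = f"t{t:g}_r{r}"
            out.append(
                QpcrMeasurement(
                    sample_id=sample,
                    target=target,
                    time_h=float(t),
                    replicate=r,
                    ct=ct0 - math.log2(observed),
                )
            )
            out.append(
                QpcrMeasurement(
                    sample_id=sample,
                    target=reference,
                    time_h=float(t),
                    replicate=r,
                    ct=ct0,
                )
            )
    return out
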