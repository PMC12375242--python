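"""Seeded synthetic sequence generation for end-to-end, download-free testing.

Transcripts are built with an exact base composition hitting the GC target
and then shuffled under the seed, so composition is deterministic and
on-target; requested implants are written verbatim at their 1-based
positions afterwards. Background decoys are produced by rejection
sampling — a candidate sharing any k-mer with the protected sequence is
discarded and redrawn — which keeps base composition unbiased rather than
post-editing collisions away.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .seqcore import NucleicSequence, Role


class FixtureError(ValueError):
    """Raised for impossible fixture specifications."""


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic trigger plus decoy background.

    Identical spec (including seed) always yields identical bytes.
    """

    seed: int = 0
    length: int = 500
    gc: float = 0.5
    implants: tuple[tuple[int, str], ...] = ()  # (1-based position, sequence)
    background_count: int = 10
    background_length: int = 400
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        for pos, seq in self.implants:
            if pos < 1 or pos + len(seq) - 1 > self.length:
                raise FixtureError(
                    f"implant at {pos} (+{len(seq)} nt) exceeds transcript "
                    f"length {self.length}"
                )
        spans = sorted((pos, pos + len(seq) - 1) for pos, seq in self.implants)
        for (alo, ahi), (blo, bhi) in zip(spans, spans[1:]):
            if blo <= ahi:
                raise FixtureError(
                    f"implants overlap: [{alo},{ahi}] and [{blo},{bhi}]"
                )


def _random_residues(rng: random.Random, length: int, gc: float) -> str:
    """Exact-composition random sequence: GC count = round(gc * length)."""
    n_gc = round(gc * length)
    n_au = length - n_gc
    pool = (
        ["G"] * (n_gc // 2)
        + ["C"] * (n_gc - n_gc // 2)
        + ["A"] * (n_au // 2)
        + ["U"] * (n_au - n_au // 2)
    )
    rng.shuffle(pool)
    return "".join(pool)


def synth_transcript(spec: FixtureSpec, id: str = "synthetic_trigger") -> NucleicSequence:
    """Generate one synthetic trigger transcript per the spec."""
    rng = random.Random(spec.seed)
    residues = list(_random_residues(rng, spec.length, spec.gc))
    for pos, seq in spec.implants:
        residues[pos - 1 : pos - 1 + len(seq)] = list(seq.replace("T", "U").upper())
    return NucleicSequence(id=id, residues="".join(residues), role=Role.TRIGGER)


def _kmers(residues: str, k: int) -> set[str]:
    return {residues[i : i + k] for i in range(len(residues) - k + 1)}


def synth_background(
    spec: FixtureSpec,
    protected: NucleicSequence | None = None,
    k: int = 15,
    offtarget_implants: tuple[tuple[int, int, str], ...] = (),
) -> list[NucleicSequence]:
    """Generate decoy background transcripts.

    When ``protected`` is given, every decoy is guaranteed (by rejection
    sampling, capped at ``spec.max_attempts`` redraws per decoy) to share
    no k-mer with it — so the protected sensor screens clean against this
    background. ``offtarget_implants`` of (decoy index, 1-based position,
    sequence) deliberately plant hits afterwards.
    """
    rng = random.Random(spec.seed + 7919)  # distinct stream from the trigger
    forbidden: set[str] = set()
    if protected is not None:
        # both strands, matching the both-strand off-target screen
        from .seqcore import reverse_complement

        forbidden = _kmers(protected.residues, k) | _kmers(
            reverse_complement(protected).residues, k
        )
    decoys: list[NucleicSequence] = []
    for idx in range(spec.background_count):
        for attempt in range(spec.max_attempts):
            candidate = _random_residues(rng, spec.background_length, spec.gc)
            if not forbidden or _kmers(candidate, k).isdisjoint(forbidden):
                break
        else:
            raise FixtureError(
                f"could not draw a k-mer-free decoy in {spec.max_attempts} attempts"
            )
        decoys.append(
            NucleicSequence(id=f"decoy_{idx}", residues=candidate, role=Role.BACKGROUND)
        )
    for idx, pos, seq in offtarget_implants:
        target = decoys[idx]
        residues = list(target.residues)
        if pos < 1 or pos + len(seq) - 1 > len(residues):
            raise FixtureError(f"off-target implant at {pos} exceeds decoy {idx}")
        residues[pos - 1 : pos - 1 + len(seq)] = list(seq.replace("T", "U").upper())
        decoys[idx] = NucleicSequence(
            id=target.id, residues="".join(residues), role=Role.BACKGROUND
        )
    return decoys
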