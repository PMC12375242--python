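"""Build and verify the three-strand Cond-siRNA construct.

A Cond-siRNA is a three-strand riboswitch. The *guide* is the antisense
siRNA strand against the silencing target, 5'-extended to a 23-bp Dicer
substrate plus a 3' dinucleotide overhang. The *sensor* is the reverse
complement of a 31-33 nt window of the trigger mRNA: its first 23 bases
clamp the core, the remainder is the exposed single-stranded toehold where
the trigger initiates strand displacement. The *core* carries three
segments read 5'->3': a 5' overhang pairing sensor bases 1..11, a central
23-mer pairing the guide, and a 3' overhang pairing sensor bases 12..23.

All coordinates are 1-based inclusive; every asserted duplex is perfect
Watson-Crick and antiparallel, and assembly re-checks this base by base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .seqcore import (
    NucleicSequence,
    Role,
    complement_base,
    gc_fraction,
    reverse_complement,
)
from . import thermo as _thermo

#: Length of the guide pairing region (the Dicer-substrate duplex).
GUIDE_PAIRING_REGION = 23
DEFAULT_OVERHANG = "UU"


class ConstructError(ValueError):
    """Raised when strand geometry or complementarity is violated."""


@dataclass(frozen=True)
class GuideStrand:
    """Guide strand: 23-nt pairing region + 3' dinucleotide overhang."""

    sequence: NucleicSequence
    pairing_region: int = GUIDE_PAIRING_REGION

    def __post_init__(self) -> None:
        if len(self.sequence) < self.pairing_region:
            raise ConstructError(
                f"guide length {len(self.sequence)} shorter than pairing "
                f"region {self.pairing_region}"
            )

    @property
    def overhang(self) -> str:
        return self.sequence.residues[self.pairing_region :]


@dataclass(frozen=True)
class SensorStrand:
    """Sensor strand: core-paired prefix (default 23 nt) + 3' toehold."""

    sequence: NucleicSequence
    core_paired: int = GUIDE_PAIRING_REGION

    def __post_init__(self) -> None:
        if len(self.sequence) <= self.core_paired:
            raise ConstructError(
                f"sensor length {len(self.sequence)} leaves no toehold beyond "
                f"the {self.core_paired} core-paired bases"
            )

    @property
    def toehold(self) -> str:
        return self.sequence.residues[self.core_paired :]


@dataclass(frozen=True)
class CoreStrand:
    """Core strand: sensor-clamping overhangs flanking the guide-pairing 23-mer."""

    sequence: NucleicSequence
    overhang5: int = 11
    central: int = GUIDE_PAIRING_REGION
    overhang3: int = 12

    def __post_init__(self) -> None:
        expected = self.overhang5 + self.central + self.overhang3
        if len(self.sequence) != expected:
            raise ConstructError(
                f"core length {len(self.sequence)} != "
                f"{self.overhang5}+{self.central}+{self.overhang3}"
            )


@dataclass(frozen=True)
class Duplex:
    """One asserted antiparallel duplex: range on strand A vs range on B.

    Position ``a_start + t`` on A pairs position ``b_end - t`` on B.
    """

    strand_a: str
    a_range: tuple[int, int]
    strand_b: str
    b_range: tuple[int, int]

    def __post_init__(self) -> None:
        la = self.a_range[1] - self.a_range[0] + 1
        lb = self.b_range[1] - self.b_range[0] + 1
        if la != lb or la < 1:
            raise ConstructError(f"duplex ranges of unequal length: {self}")

    def __len__(self) -> int:
        return self.a_range[1] - self.a_range[0] + 1


@dataclass(frozen=True)
class PairingMap:
    """The full set of duplexes asserted by a construct design."""

    duplexes: tuple[Duplex, ...]

    def __post_init__(self) -> None:
        claimed: set[tuple[str, int]] = set()
        for d in self.duplexes:
            for strand, (lo, hi) in (
                (d.strand_a, d.a_range),
                (d.strand_b, d.b_range),
            ):
                for pos in range(lo, hi + 1):
                    key = (strand, pos)
                    if key in claimed:
                        raise ConstructError(
                            f"position {pos} of {strand} claimed by two duplexes"
                        )
                    claimed.add(key)


@dataclass(frozen=True)
class CondSiRNAConstruct:
    guide: GuideStrand
    sensor: SensorStrand
    core: CoreStrand
    pairing: PairingMap
    stats: dict = field(default_factory=dict)

    def clamp_split(self) -> tuple[int, int]:
        """Lengths of the core 5' and 3' sensor-clamping overhangs."""
        return self.core.overhang5, self.core.overhang3

    def strand(self, name: str) -> NucleicSequence:
        return {
            "guide": self.guide.sequence,
            "sensor": self.sensor.sequence,
            "core": self.core.sequence,
        }[name]

    def to_json(self) -> str:
        doc = {
            "guide": {"id": self.guide.sequence.id, "seq": self.guide.sequence.residues},
            "sensor": {
                "id": self.sensor.sequence.id,
                "seq": self.sensor.sequence.residues,
            },
            "core": {"id": self.core.sequence.id, "seq": self.core.sequence.residues},
            "pairing": [
                {
                    "a": d.strand_a,
                    "a_range": list(d.a_range),
                    "b": d.strand_b,
                    "b_range": list(d.b_range),
                }
                for d in self.pairing.duplexes
            ],
            "stats": self.stats,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CondSiRNAConstruct":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConstructError(f"malformed construct JSON: {exc}") from exc
        for key in ("guide", "sensor", "core"):
            if key not in doc or "seq" not in doc[key]:
                raise ConstructError(f"construct JSON missing {key}.seq")
        guide = NucleicSequence(doc["guide"].get("id", "guide"), doc["guide"]["seq"], Role.GUIDE)
        sensor = NucleicSequence(
            doc["sensor"].get("id", "sensor"), doc["sensor"]["seq"], Role.SENSOR
        )
        core = NucleicSequence(doc["core"].get("id", "core"), doc["core"]["seq"], Role.CORE)
        return assemble_construct(
            GuideStrand(guide),
            SensorStrand(sensor),
            _core_from_sequence(core, len(sensor)),
        )


def _core_from_sequence(core: NucleicSequence, sensor_len: int) -> CoreStrand:
    clamp = len(core) - GUIDE_PAIRING_REGION
    if clamp < 2:
        raise ConstructError(f"core of {len(core)} nt too short for any clamp")
    return CoreStrand(
        core,
        overhang5=clamp // 2,
        central=GUIDE_PAIRING_REGION,
        overhang3=clamp - clamp // 2,
    )


def build_sensor(window) -> SensorStrand:
    """Derive the sensor strand from a trigger window (reverse complement).

    ``window`` may be a :class:`~condsirna.screen.TriggerWindow` or a bare
    :class:`NucleicSequence`. At least 24 nt are required: 23 bases clamp
    the core, and at least one base must remain as toehold.
    """
    seq = getattr(window, "sequence", window)
    if len(seq) < GUIDE_PAIRING_REGION + 1:
        raise ConstructError(
            f"window of {len(seq)} nt cannot yield a sensor: {GUIDE_PAIRING_REGION} "
            "bases must pair the core and at least one toehold base must remain"
        )
    sensor = reverse_complement(seq, id=f"{seq.id}_sensor").with_role(Role.SENSOR)
    return SensorStrand(sensor)


def _gc_rich(extension: str, min_frac: float = 0.75) -> bool:
    if not extension:
        return True
    gc = sum(b in "GC" for b in extension)
    return gc / len(extension) >= min_frac


def choose_extension(sirna_guide: NucleicSequence, length: int) -> str:
    """Pick a 5' extension from {G, C} maximizing duplex stability.

    All ``2**length`` G/C strings are scored by the nearest-neighbor free
    energy of the extended pairing region against its perfect complement;
    the most stable wins, ties broken G before C (first in enumeration
    order). Lengths above 12 are rejected — supply an explicit extension.
    """
    if length == 0:
        return ""
    if length > 12:
        raise ConstructError("auto-extension supported only up to 12 nt")
    from itertools import product

    table = _thermo.load_nn_table()
    best: tuple[float, str] | None = None
    for combo in product("GC", repeat=length):
        ext = "".join(combo)
        region = NucleicSequence("ext", ext + sirna_guide.residues)
        dg = _thermo.duplex_dG(region, reverse_complement(region), table)
        if best is None or dg < best[0]:
            best = (dg, ext)
    return best[1]


def build_guide(
    sirna_guide: NucleicSequence,
    extension: NucleicSequence | str | None = None,
    overhang: str = DEFAULT_OVERHANG,
    enforce_gc_rich: bool = True,
) -> GuideStrand:
    """Extend a validated siRNA guide into the full Dicer-substrate guide.

    The final guide is ``extension + siRNA (+ overhang)``: a 23-nt
    Dicer-substrate pairing region followed by a 3' dinucleotide overhang
    (default UU). Validated siRNA guides are accepted either without their
    overhang (extension + siRNA totals 23 nt; the overhang is appended) or
    with it already present, as in a classic 21-mer (extension + siRNA
    totals 23 + len(overhang); nothing is appended). If no extension is
    supplied, one is chosen from G/C bases to maximize duplex stability.
    With ``enforce_gc_rich`` a supplied extension must be at least 3/4 G
    or C.
    """
    target = GUIDE_PAIRING_REGION + len(overhang)
    if extension is None:
        if len(sirna_guide) > GUIDE_PAIRING_REGION:
            raise ConstructError(
                f"siRNA guide of {len(sirna_guide)} nt exceeds the "
                f"{GUIDE_PAIRING_REGION}-nt pairing region"
            )
        ext = choose_extension(sirna_guide, GUIDE_PAIRING_REGION - len(sirna_guide))
        residues = ext + sirna_guide.residues + overhang
    else:
        ext = extension.residues if isinstance(extension, NucleicSequence) else str(extension)
        total = len(ext) + len(sirna_guide)
        if total == GUIDE_PAIRING_REGION:
            residues = ext + sirna_guide.residues + overhang
        elif total == target:
            residues = ext + sirna_guide.residues
        else:
            raise ConstructError(
                f"extension of {len(ext)} nt plus siRNA of {len(sirna_guide)} nt "
                f"must total {GUIDE_PAIRING_REGION} (overhang appended) or "
                f"{target} (overhang included), got {total}"
            )
        if enforce_gc_rich and not _gc_rich(ext):
            raise ConstructError(
                f"extension {ext!r} is not GC-rich (fewer than 3 of 4 bases G/C)"
            )
    full = NucleicSequence(
        id=f"{sirna_guide.id}_guide",
        residues=residues,
        role=Role.GUIDE,
    )
    return GuideStrand(full)


def build_core(sensor: SensorStrand, guide: GuideStrand) -> CoreStrand:
    """Assemble the core strand from the sensor and guide.

    core = revcomp(sensor[1..floor(P/2)]) + revcomp(guide[1..23]) +
    revcomp(sensor[floor(P/2)+1..P]) where P is the sensor core-paired
    region (default 23, giving the 11/12 split).
    """
    p = sensor.core_paired
    len5, len3 = p // 2, p - p // 2
    seg5 = reverse_complement(sensor.sequence.subseq(1, len5))
    central = reverse_complement(guide.sequence.subseq(1, guide.pairing_region))
    seg3 = reverse_complement(sensor.sequence.subseq(len5 + 1, p))
    core = NucleicSequence(
        id=f"{sensor.sequence.id}_core",
        residues=seg5.residues + central.residues + seg3.residues,
        role=Role.CORE,
    )
    return CoreStrand(core, overhang5=len5, central=guide.pairing_region, overhang3=len3)


def _check_duplex(d: Duplex, seq_a: NucleicSequence, seq_b: NucleicSequence) -> None:
    a0, a1 = d.a_range
    b0, b1 = d.b_range
    for t in range(len(d)):
        pa, pb = a0 + t, b1 - t
        base_a = seq_a.residues[pa - 1]
        base_b = seq_b.residues[pb - 1]
        if complement_base(base_a) != base_b:
            raise ConstructError(
                f"duplex mismatch: {d.strand_a} position {pa} ({base_a}) does "
                f"not pair {d.strand_b} position {pb} ({base_b})"
            )


def assemble_construct(
    guide: GuideStrand, sensor: SensorStrand, core: CoreStrand
) -> CondSiRNAConstruct:
    """Assemble and verify the three strands into a construct.

    Asserts exactly three duplexes — core 5' overhang vs sensor prefix,
    core central vs guide pairing region, core 3' overhang vs the rest of
    the sensor clamp — and verifies Watson-Crick complementarity at every
    position. Any mismatch raises :class:`ConstructError` naming the first
    offending position pair.
    """
    len5, central, len3 = core.overhang5, core.central, core.overhang3
    if len5 + len3 != sensor.core_paired:
        raise ConstructError(
            f"core overhangs {len5}+{len3} do not cover the sensor's "
            f"{sensor.core_paired} core-paired bases"
        )
    if central != guide.pairing_region:
        raise ConstructError(
            f"core central segment {central} != guide pairing region "
            f"{guide.pairing_region}"
        )
    duplexes = (
        Duplex("core", (1, len5), "sensor", (1, len5)),
        Duplex("core", (len5 + 1, len5 + central), "guide", (1, central)),
        Duplex(
            "core",
            (len5 + central + 1, len5 + central + len3),
            "sensor",
            (len5 + 1, len5 + len3),
        ),
    )
    strands = {
        "guide": guide.sequence,
        "sensor": sensor.sequence,
        "core": core.sequence,
    }
    for d in duplexes:
        _check_duplex(d, strands[d.strand_a], strands[d.strand_b])
    pairing = PairingMap(duplexes)
    stats = {
        "duplex_lengths": [len(d) for d in duplexes],
        "toehold": sensor.toehold,
        "toehold_length": len(sensor.toehold),
        "guide_overhang": guide.overhang,
        "sensor_paired_bases": sensor.core_paired,
        "nick_positions_on_core": [len5, len5 + central],
    }
    return CondSiRNAConstruct(
        guide=guide, sensor=sensor, core=core, pairing=pairing, stats=stats
    )


def verify_assembly(c: CondSiRNAConstruct, table=None) -> dict:
    """Produce a verification report for an assembled construct.

    Reports each duplex with its length and nearest-neighbor ΔG°37, the
    unpaired regions (toehold, guide overhang, core nick positions), and
    pass/fail flags against the design geometry (23-bp Dicer duplex, first
    23 sensor bases paired). Advisory deviations (e.g. a non-UU guide
    overhang) appear as warnings, never failures.
    """
    table = table or _thermo.load_nn_table()
    strands = {
        "guide": c.guide.sequence,
        "sensor": c.sensor.sequence,
        "core": c.core.sequence,
    }
    duplex_reports = []
    for d in c.pairing.duplexes:
        a = strands[d.strand_a].subseq(*d.a_range)
        b = strands[d.strand_b].subseq(*d.b_range)
        duplex_reports.append(
            {
                "a": d.strand_a,
                "a_range": list(d.a_range),
                "b": d.strand_b,
                "b_range": list(d.b_range),
                "length": len(d),
                "dG37_kcal_mol": round(_thermo.duplex_dG(a, reverse_complement(a), table), 2),
            }
        )
    central = next(len(d) for d in c.pairing.duplexes if d.strand_b == "guide")
    checks = {
        "dicer_duplex_23bp": central == GUIDE_PAIRING_REGION,
        "sensor_first_23_paired": c.sensor.core_paired == GUIDE_PAIRING_REGION
        and sum(len(d) for d in c.pairing.duplexes if d.strand_b == "sensor")
        == c.sensor.core_paired,
        "toehold_present": len(c.sensor.toehold) >= 1,
    }
    warnings = []
    if c.guide.overhang != DEFAULT_OVERHANG:
        warnings.append(
            f"guide 3' overhang {c.guide.overhang!r} differs from the usual UU"
        )
    return {
        "duplexes": duplex_reports,
        "unpaired": {
            "toehold": c.sensor.toehold,
            "guide_overhang": c.guide.overhang,
            "core_nick_positions": c.stats.get("nick_positions_on_core", []),
        },
        "checks": checks,
        "pass": all(checks.values()),
        "warnings": warnings,
    }
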