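"""Chemical-modification representation, presets, and vendor-style notation.

A :class:`ModifiedStrand` decorates a plain RNA strand with per-residue
sugar chemistry (ribose, 2'-O-methyl, LNA), per-linkage backbone chemistry
(phosphodiester or phosphorothioate), and optional terminal conjugates
(cholesterol-TEG, fluorophore). The base sequence is never altered.

Serialization uses a compact vendor-style notation::

    mA*+C GU [3'chol-TEG]

* ``m`` prefix: 2'-O-methyl sugar; ``+`` prefix: LNA; bare letter: ribose
* ``*`` after a residue: the following backbone linkage is phosphorothioate
* ``[5'<tag>]`` / ``[3'<tag>]``: terminal conjugate tags

Modification presets for the three construct generations (firstG, secondG,
cholConj) ship as an editable YAML data asset; the exact per-position
defaults are illustrative, encoding each generation's qualitative pattern.
The "middle toehold" region is interpreted as the sensor residue sitting at
the nick between the core's central and 3' segments.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .construct import CondSiRNAConstruct
from .seqcore import NucleicSequence


class ModificationError(ValueError):
    """Raised for malformed notation or unresolvable preset regions."""


class Sugar(str, enum.Enum):
    RIBO = "ribo"
    OME2 = "2OMe"
    LNA = "LNA"


class Backbone(str, enum.Enum):
    PO = "PO"
    PS = "PS"


class Conjugate(str, enum.Enum):
    NONE = "none"
    CHOL_TEG = "chol-TEG"
    FLUOROPHORE = "FAM"


_SUGAR_PREFIX = {Sugar.RIBO: "", Sugar.OME2: "m", Sugar.LNA: "+"}
_PREFIX_SUGAR = {"m": Sugar.OME2, "+": Sugar.LNA}


@dataclass(frozen=True)
class ModifiedStrand:
    """A strand plus its chemistry vectors.

    ``sugar`` has one entry per residue; ``backbone`` one per internal
    linkage (residues - 1); conjugates attach at the termini.
    """

    base: NucleicSequence
    sugar: tuple[Sugar, ...]
    backbone: tuple[Backbone, ...]
    conjugate5: Conjugate = Conjugate.NONE
    conjugate3: Conjugate = Conjugate.NONE

    def __post_init__(self) -> None:
        n = len(self.base)
        if len(self.sugar) != n:
            raise ModificationError(
                f"sugar vector length {len(self.sugar)} != {n} residues"
            )
        if len(self.backbone) != max(n - 1, 0):
            raise ModificationError(
                f"backbone vector length {len(self.backbone)} != {max(n - 1, 0)} linkages"
            )

    @classmethod
    def plain(cls, base: NucleicSequence) -> "ModifiedStrand":
        n = len(base)
        return cls(
            base=base,
            sugar=(Sugar.RIBO,) * n,
            backbone=(Backbone.PO,) * max(n - 1, 0),
        )


def serialize_notation(m: ModifiedStrand) -> str:
    """Render a modified strand in the compact vendor-style notation."""
    out = []
    if m.conjugate5 is not Conjugate.NONE:
        out.append(f"[5'{m.conjugate5.value}]")
    for i, base in enumerate(m.base.residues):
        out.append(_SUGAR_PREFIX[m.sugar[i]] + base)
        if i < len(m.backbone) and m.backbone[i] is Backbone.PS:
            out.append("*")
    if m.conjugate3 is not Conjugate.NONE:
        out.append(f"[3'{m.conjugate3.value}]")
    return "".join(out)


_TAG_RE = re.compile(r"\[(5'|3')([^\]]+)\]")


def parse_notation(text: str, id: str = "strand") -> ModifiedStrand:
    """Parse notation text back into a :class:`ModifiedStrand`.

    ``parse_notation(serialize_notation(m)) == m`` for every valid strand.
    Malformed tokens are rejected with their character position.
    """
    conj5 = conj3 = Conjugate.NONE
    residues: list[str] = []
    sugars: list[Sugar] = []
    ps_after: list[bool] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            match = _TAG_RE.match(text, i)
            if not match:
                raise ModificationError(f"malformed conjugate tag at position {i + 1}")
            end, tag = match.group(1), match.group(2)
            try:
                conj = Conjugate(tag)
            except ValueError:
                raise ModificationError(
                    f"unknown conjugate {tag!r} at position {i + 1}"
                ) from None
            if end == "5'":
                if residues:
                    raise ModificationError(
                        f"5' conjugate tag not at strand start (position {i + 1})"
                    )
                conj5 = conj
            else:
                conj3 = conj
            i = match.end()
            continue
        if ch == "*":
            if not residues or ps_after[-1]:
                raise ModificationError(f"stray '*' at position {i + 1}")
            ps_after[-1] = True
            i += 1
            continue
        sugar = Sugar.RIBO
        if ch in _PREFIX_SUGAR:
            sugar = _PREFIX_SUGAR[ch]
            i += 1
            if i >= len(text):
                raise ModificationError(f"dangling sugar prefix at position {i}")
            ch = text[i]
        if ch not in "ACGU":
            raise ModificationError(f"unexpected symbol {ch!r} at position {i + 1}")
        if conj3 is not Conjugate.NONE:
            raise ModificationError(
                f"residue after 3' conjugate tag at position {i + 1}"
            )
        residues.append(ch)
        sugars.append(sugar)
        ps_after.append(False)
        i += 1
    if not residues:
        raise ModificationError("no residues in notation text")
    if ps_after[-1]:
        raise ModificationError("'*' after the last residue has no linkage")
    backbone = tuple(
        Backbone.PS if ps else Backbone.PO for ps in ps_after[:-1]
    )
    return ModifiedStrand(
        base=NucleicSequence(id, "".join(residues)),
        sugar=tuple(sugars),
        backbone=backbone,
        conjugate5=conj5,
        conjugate3=conj3,
    )


@dataclass(frozen=True)
class ModificationPreset:
    """Named, data-driven rule set mapping regions to chemistry."""

    name: str
    description: str
    rules: tuple[dict, ...]


def load_presets(name: str = "presets.yaml") -> dict[str, ModificationPreset]:
    """Load the shipped preset asset (firstG, secondG, cholConj)."""
    text = resources.files("condsirna.data").joinpath(name).read_text()
    doc = yaml.safe_load(text)
    presets = {}
    for pname, body in doc["presets"].items():
        presets[pname] = ModificationPreset(
            name=pname,
            description=body.get("description", ""),
            rules=tuple(body.get("rules", ())),
        )
    return presets


def _resolve_region(
    c: CondSiRNAConstruct, strand: str, region: str
) -> tuple[int, int]:
    """Resolve a named region to a 1-based inclusive position range."""
    n = len(c.strand(strand))
    len5, len3 = c.clamp_split()
    regions: dict[tuple[str, str], tuple[int, int]] = {
        ("guide", "all"): (1, n),
        ("sensor", "all"): (1, n),
        ("core", "all"): (1, n),
        ("guide", "pairing_region"): (1, c.guide.pairing_region),
        ("guide", "overhang"): (c.guide.pairing_region + 1, len(c.guide.sequence)),
        ("sensor", "toehold"): (c.sensor.core_paired + 1, len(c.sensor.sequence)),
        ("sensor", "clamp"): (1, c.sensor.core_paired),
        # The clamp base at the nick between the core's central and 3'
        # segments; an interpretation of the "middle toehold" locus.
        ("sensor", "middle_toehold"): (c.sensor.core_paired, c.sensor.core_paired),
        ("core", "overhang5"): (1, len5),
        ("core", "central"): (len5 + 1, len5 + c.core.central),
        ("core", "overhang3"): (len5 + c.core.central + 1, len(c.core.sequence)),
    }
    if region == "middle_toehold" and not c.stats.get("nick_positions_on_core"):
        raise ModificationError(
            "middle_toehold requires a construct with a recorded nick annotation"
        )
    try:
        lo, hi = regions[(strand, region)]
    except KeyError:
        raise ModificationError(
            f"region {region!r} does not resolve on strand {strand!r}"
        ) from None
    if not (1 <= lo <= hi <= n):
        raise ModificationError(f"region {region!r} empty on this construct")
    return lo, hi


def apply_preset(
    c: CondSiRNAConstruct, preset: ModificationPreset
) -> dict[str, ModifiedStrand]:
    """Apply a preset's rules to a construct; returns one record per strand.

    Deterministic and idempotent: rules apply in order onto all-ribose /
    all-phosphodiester defaults, and re-application reproduces the same
    output. Backbone rules modify the linkages internal to the selected
    residue range.
    """
    state = {}
    for name in ("guide", "sensor", "core"):
        seq = c.strand(name)
        state[name] = {
            "sugar": [Sugar.RIBO] * len(seq),
            "backbone": [Backbone.PO] * max(len(seq) - 1, 0),
            "conj5": Conjugate.NONE,
            "conj3": Conjugate.NONE,
        }
    for rule in preset.rules:
        strand = rule.get("strand")
        if strand not in state:
            raise ModificationError(f"rule names unknown strand {strand!r}")
        st = state[strand]
        if "conjugate5" in rule:
            st["conj5"] = Conjugate(rule["conjugate5"])
        if "conjugate3" in rule:
            st["conj3"] = Conjugate(rule["conjugate3"])
        if "region" in rule:
            lo, hi = _resolve_region(c, strand, rule["region"])
        elif "positions" in rule:
            lo, hi = rule["positions"]
            if not (1 <= lo <= hi <= len(c.strand(strand))):
                raise ModificationError(
                    f"positions [{lo}, {hi}] out of range on {strand}"
                )
        else:
            if "conjugate5" in rule or "conjugate3" in rule:
                continue
            raise ModificationError(f"rule selects no positions: {rule}")
        if "sugar" in rule:
            sugar = Sugar(rule["sugar"])
            for p in range(lo, hi + 1):
                st["sugar"][p - 1] = sugar
        if "backbone" in rule:
            backbone = Backbone(rule["backbone"])
            for p in range(lo, hi):  # linkages internal to the range
                st["backbone"][p - 1] = backbone
    return {
        name: ModifiedStrand(
            base=c.strand(name),
            sugar=tuple(st["sugar"]),
            backbone=tuple(st["backbone"]),
            conjugate5=st["conj5"],
            conjugate3=st["conj3"],
        )
        for name, st in state.items()
    }


def validate_modified_strand(m: ModifiedStrand, policy: dict | None = None) -> list[str]:
    """Advisory checks; returns warnings, never raises, never blocks export."""
    policy = policy or {}
    warnings = []
    if m.conjugate5 is not Conjugate.NONE and m.conjugate3 is not Conjugate.NONE:
        warnings.append("conjugates on both termini")
    max_lna = policy.get("max_lna_fraction", 0.5)
    if len(m.base) and sum(s is Sugar.LNA for s in m.sugar) / len(m.base) > max_lna:
        warnings.append(f"LNA fraction exceeds {max_lna:.0%}")
    return warnings
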