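"""Nearest-neighbor duplex free energies and a maximum-pairing fold screen.

Two small models cover everything the design pipeline needs:

* a nearest-neighbor (NN) duplex model for *perfect* Watson-Crick duplexes —
  Gibbs free energy at 37 C as initiation + stacked dinucleotide terms +
  terminal A·U penalties, with parameters shipped as a versioned TSV asset;
* a Nussinov-style maximum base-pairing dynamic program used as a
  secondary-structure screen (the designed strands should be close to
  unstructured on their own).

All designed duplexes in a Cond-siRNA construct are perfect by
construction, so internal loops and bulges are deliberately out of scope.
A net strand-displacement score compares the trigger:sensor duplex a
construct would gain against the two sensor:core clamp duplexes it must
give up; a negative net value means displacement is downhill.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .seqcore import (
    NucleicSequence,
    complement_base,
    reverse_complement,
)

_STEPS = tuple(a + b for a in "ACGU" for b in "ACGU")


class ThermoError(ValueError):
    """Raised for invalid thermodynamic inputs (non-complementary duplexes, ...)."""


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor ΔG°37 parameters for RNA/RNA Watson-Crick duplexes.

    ``stacks`` maps each of the 16 dinucleotide steps (keyed by the 5'->3'
    dinucleotide on the reference strand; the partner strand is its exact
    complement) to a stacking free energy in kcal/mol. ``initiation`` is the
    duplex-initiation cost and ``terminal_au`` the per-end penalty for a
    terminal A·U pair. ``source`` records provenance of the asset file.
    """

    stacks: dict[str, float]
    initiation: float
    terminal_au: float
    source: str = "unknown"

    def __post_init__(self) -> None:
        missing = [s for s in _STEPS if s not in self.stacks]
        if missing:
            raise ThermoError(f"parameter table missing stack steps: {missing}")
        for step, val in self.stacks.items():
            if val != val or val in (float("inf"), float("-inf")):
                raise ThermoError(f"non-finite stack value for {step}")


def load_nn_table(name: str = "rna_nn_dG37.tsv") -> NNParameterTable:
    """Load the shipped nearest-neighbor parameter asset."""
    text = resources.files("condsirna.data").joinpath(name).read_text()
    source_lines = []
    stacks: dict[str, float] = {}
    initiation = terminal_au = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            source_lines.append(line.lstrip("# "))
            continue
        key, _, value = line.partition("\t")
        if key == "step":  # column header
            continue
        if key == "INIT":
            initiation = float(value)
        elif key == "TERM_AU":
            terminal_au = float(value)
        else:
            stacks[key] = float(value)
    if initiation is None or terminal_au is None:
        raise ThermoError(f"asset {name} lacks INIT/TERM_AU rows")
    return NNParameterTable(
        stacks=stacks,
        initiation=initiation,
        terminal_au=terminal_au,
        source=" | ".join(source_lines[:3]) or name,
    )


def duplex_dG(
    a: NucleicSequence, b: NucleicSequence, table: NNParameterTable | None = None
) -> float:
    """ΔG°37 (kcal/mol) of the perfect duplex of ``a`` with ``b``.

    ``b`` must be the exact reverse complement of ``a`` and the duplex must
    be at least 2 bp (a single pair has no stack). The sum runs 5'->3' on
    strand ``a``: initiation + one stack term per dinucleotide step + a
    terminal A·U penalty for each helix end closed by an A·U pair.
    """
    table = table or load_nn_table()
    if len(a) < 2:
        raise ThermoError("duplex must be at least 2 bp (no stack defined)")
    if len(a) != len(b):
        raise ThermoError(f"strand lengths differ: {len(a)} vs {len(b)}")
    for i, base_a in enumerate(a.residues):
        base_b = b.residues[len(b) - 1 - i]
        if complement_base(base_a) != base_b:
            raise ThermoError(
                f"strands not complementary: position {i + 1} of {a.id!r} "
                f"({base_a}) vs position {len(b) - i} of {b.id!r} ({base_b})"
            )
    dg = table.initiation
    for i in range(len(a) - 1):
        dg += table.stacks[a.residues[i : i + 2]]
    if a.residues[0] in "AU":
        dg += table.terminal_au
    if a.residues[-1] in "AU":
        dg += table.terminal_au
    return dg


@dataclass(frozen=True)
class FoldResult:
    """Outcome of the maximum-pairing fold screen for one sequence."""

    sequence_id: str
    max_pairs: int
    structure: str
    min_loop: int

    def __post_init__(self) -> None:
        if self.structure.count("(") != self.max_pairs:
            raise ThermoError("structure pair count disagrees with max_pairs")


def _can_pair(x: str, y: str, wobble: bool) -> bool:
    if complement_base(x) == y:
        return True
    return wobble and {x, y} == {"G", "U"}


def nussinov_fold(
    s: NucleicSequence, min_loop: int = 3, wobble: bool = False
) -> FoldResult:
    """Maximum number of nested base pairs with hairpin loops >= ``min_loop``.

    Watson-Crick pairs only by default; ``wobble=True`` also admits G·U.
    One optimal structure is recovered by a deterministic traceback that
    prefers pairing the 5'-most base, with the 5'-most admissible partner.
    """
    n = len(s)
    seq = s.residues
    # N[i][j]: max pairs on seq[i..j] (0-based inclusive)
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(seq[i], seq[k], wobble):
                    left = N[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    cand = left + right + 1
                    if cand > best:
                        best = cand
            N[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(seq[i], seq[k], wobble):
                left = N[i + 1][k - 1] if k - 1 >= i + 1 else 0
                right = N[k + 1][j] if k + 1 <= j else 0
                if left + right + 1 == N[i][j]:
                    structure[i], structure[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))

    max_pairs = N[0][n - 1] if n else 0
    return FoldResult(
        sequence_id=s.id,
        max_pairs=max_pairs,
        structure="".join(structure),
        min_loop=min_loop,
    )


def fold_score(s: NucleicSequence, min_loop: int = 3) -> int:
    """Convenience: maximum self-pairing count used as the screen metric."""
    return nussinov_fold(s, min_loop=min_loop).max_pairs


@dataclass(frozen=True)
class DisplacementScore:
    """Free-energy bookkeeping for trigger-driven sensor displacement.

    ``net_ddG = dG_trigger_sensor - (dG_core5_duplex + dG_core3_duplex)``;
    a negative net value means the trigger:sensor duplex formed is more
    stable than the two sensor:core clamp duplexes broken, i.e. the switch
    opens downhill.
    """

    dG_trigger_sensor: float
    dG_core5_duplex: float
    dG_core3_duplex: float

    @property
    def net_ddG(self) -> float:
        return self.dG_trigger_sensor - (self.dG_core5_duplex + self.dG_core3_duplex)


def displacement_ddG(construct, trigger_window, table: NNParameterTable | None = None):
    """Score sensor displacement of a construct by its trigger window.

    ``construct`` is a :class:`~condsirna.construct.CondSiRNAConstruct`;
    ``trigger_window`` a :class:`~condsirna.screen.TriggerWindow` (or any
    object with a ``sequence`` attribute) whose sequence must be the exact
    reverse complement of the construct's sensor.
    """
    table = table or load_nn_table()
    sensor = construct.sensor.sequence
    window_seq = trigger_window.sequence
    if reverse_complement(window_seq).residues != sensor.residues:
        raise ThermoError(
            "trigger window is not the reverse complement of the construct sensor"
        )
    len5, len3 = construct.clamp_split()
    dg_ts = duplex_dG(sensor, window_seq, table)
    dg5 = duplex_dG(
        sensor.subseq(1, len5), reverse_complement(sensor.subseq(1, len5)), table
    )
    dg3 = duplex_dG(
        sensor.subseq(len5 + 1, len5 + len3),
        reverse_complement(sensor.subseq(len5 + 1, len5 + len3)),
        table,
    )
    return DisplacementScore(
        dG_trigger_sensor=dg_ts, dG_core5_duplex=dg5, dG_core3_duplex=dg3
    )
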