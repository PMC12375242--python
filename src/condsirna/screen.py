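"""Trigger-window enumeration, filtering, off-target screening, and ranking.

Candidate sensors come from sliding windows (default 31-33 nt) over the
trigger mRNA. Each window is scored on the strand that would actually be
synthesized — the sensor, i.e. the window's reverse complement: GC content
near 50%, absence of liability motifs (GGGG and four consecutive A/U),
low self-structure, and no exact shared k-mer with any background
transcript (a deterministic, offline stand-in for a genome-wide
similarity search; k defaults to 15).

Ranking of surviving windows is a documented, configurable policy:
closeness of GC to 0.50, then self-structure, then 5'-most start.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .seqcore import (
    DEFAULT_FORBIDDEN_MOTIFS,
    NucleicSequence,
    Role,
    find_forbidden_motifs,
    gc_fraction,
    reverse_complement,
)
from .thermo import fold_score

logger = logging.getLogger(__name__)

UNSCREENED = -1  # off-target sentinel when no background index is supplied


class ScreenError(ValueError):
    """Raised for invalid screening inputs."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and knobs for the window screen.

    window_lengths : candidate window sizes in nt (default 31-33).
    gc_bounds : inclusive [lo, hi] GC-fraction band around ~50%.
    forbidden_motifs : motifs rejected on the sensor strand (M = A or U).
    fold_ceiling : max admissible self-pairing base pairs of the sensor.
    offtarget_k : exact-match k-mer length for the background screen.
    exclude_ids : background record ids treated as the intended target.
    motifs_on_both_strands : also screen motifs on the window itself.
    """

    window_lengths: tuple[int, ...] = (31, 32, 33)
    gc_bounds: tuple[float, float] = (0.45, 0.55)
    forbidden_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN_MOTIFS
    fold_ceiling: int = 6
    offtarget_k: int = 15
    exclude_ids: tuple[str, ...] = ()
    motifs_on_both_strands: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.gc_bounds
        if not (0 < lo < hi < 1):
            raise ScreenError(f"gc_bounds must satisfy 0 < lo < hi < 1, got {self.gc_bounds}")
        if self.offtarget_k < 8:
            raise ScreenError("offtarget_k must be >= 8")
        if min(self.window_lengths) < self.offtarget_k:
            raise ScreenError("window lengths must be >= offtarget_k")


@dataclass(frozen=True)
class TriggerWindow:
    """One candidate window of the trigger, with its screen metrics."""

    source_id: str
    start: int  # 1-based on the trigger
    length: int
    sequence: NucleicSequence
    sensor: NucleicSequence | None = None
    gc: float | None = None
    motif_hits: tuple[tuple[str, int], ...] = ()
    fold: int | None = None
    offtarget_hits: int = UNSCREENED

    @property
    def evaluated(self) -> bool:
        return self.gc is not None

    def passes(self, cfg: ScreenConfig) -> bool:
        """Hard filters: GC band, motifs, off-targets (when screened).

        The fold score is advisory — it orders survivors and flags
        structured sensors against ``cfg.fold_ceiling`` but never rejects:
        maximum-pairing counts overstate real structure, and workable
        sensors can sit above any fixed ceiling.
        """
        if not self.evaluated:
            raise ScreenError("window not evaluated")
        lo, hi = cfg.gc_bounds
        if not (lo <= self.gc <= hi):
            return False
        if self.motif_hits:
            return False
        if self.offtarget_hits > 0:
            return False
        return True

    def rank_score(self) -> tuple:
        return (abs(self.gc - 0.50), self.fold, self.start, self.length)


@dataclass(frozen=True)
class KmerIndex:
    """Exact k-mer -> occurrence index over the background transcriptome."""

    k: int
    occurrences: Mapping[str, tuple[tuple[str, int], ...]]
    record_ids: tuple[str, ...]

    def lookup(self, kmer: str) -> tuple[tuple[str, int], ...]:
        return self.occurrences.get(kmer, ())


def enumerate_windows(
    trigger: NucleicSequence, cfg: ScreenConfig | None = None
) -> list[TriggerWindow]:
    """All windows of every configured length, in (start, length) order."""
    cfg = cfg or ScreenConfig()
    L = len(trigger)
    if L < min(cfg.window_lengths):
        raise ScreenError(
            f"trigger of {L} nt shorter than the smallest window "
            f"({min(cfg.window_lengths)} nt)"
        )
    windows = []
    for start in range(1, L + 1):
        for w in sorted(cfg.window_lengths):
            if start + w - 1 <= L:
                windows.append(
                    TriggerWindow(
                        source_id=trigger.id,
                        start=start,
                        length=w,
                        sequence=trigger.subseq(start, start + w - 1),
                    )
                )
    return windows


def evaluate_window(
    w: TriggerWindow, cfg: ScreenConfig, index: KmerIndex | None = None
) -> TriggerWindow:
    """Fill in GC, motif, fold, and off-target metrics for one window.

    GC is computed on the window (identical on the sensor by strand
    symmetry); motif and fold screens run on the derived sensor strand,
    the oligo that would be synthesized. Off-target hits stay at the
    ``UNSCREENED`` sentinel when no index is given.
    """
    sensor = reverse_complement(w.sequence, id=f"{w.source_id}_{w.start}_sensor")
    motif_hits = tuple(find_forbidden_motifs(sensor, cfg.forbidden_motifs))
    if cfg.motifs_on_both_strands:
        motif_hits = motif_hits + tuple(
            find_forbidden_motifs(w.sequence, cfg.forbidden_motifs)
        )
    hits = UNSCREENED
    if index is not None:
        hits = count_offtarget_hits(sensor, index, set(cfg.exclude_ids))
    return replace(
        w,
        sensor=sensor.with_role(Role.SENSOR),
        gc=gc_fraction(w.sequence),
        motif_hits=motif_hits,
        fold=fold_score(sensor),
        offtarget_hits=hits,
    )


def build_kmer_index(background: Iterable[NucleicSequence], k: int) -> KmerIndex:
    """Exhaustive exact k-mer index of the background transcriptome.

    Records shorter than k are skipped with a logged warning.
    """
    occurrences: dict[str, list[tuple[str, int]]] = {}
    ids = []
    for rec in background:
        if len(rec) < k:
            logger.warning(
                "background record %s (%d nt) shorter than k=%d; skipped",
                rec.id, len(rec), k,
            )
            continue
        ids.append(rec.id)
        for i in range(len(rec) - k + 1):
            occurrences.setdefault(rec.residues[i : i + k], []).append((rec.id, i + 1))
    if not ids:
        raise ScreenError("background is empty (or all records shorter than k)")
    return KmerIndex(
        k=k,
        occurrences={km: tuple(v) for km, v in occurrences.items()},
        record_ids=tuple(ids),
    )


def count_offtarget_hits(
    sensor: NucleicSequence, index: KmerIndex, exclusions: set[str] | None = None
) -> int:
    """Number of background records sharing >= 1 exact k-mer with the sensor."""
    return len(offtarget_hit_records(sensor, index, exclusions))


def offtarget_hit_records(
    sensor: NucleicSequence, index: KmerIndex, exclusions: set[str] | None = None
) -> dict[str, int]:
    """Per-record count of shared k-mer occurrences (the detailed report).

    Both the sensor and its reverse complement are queried: the sensor
    hybridizes transcripts carrying its complement, while an identical
    k-mer marks a transcript the sensor's own complement would bind — a
    both-strand search, as a BLAST of the sensor would perform. This is
    also what lets the intended trigger transcript itself register (and be
    excluded by id).
    """
    exclusions = exclusions or set()
    if len(sensor) < index.k:
        raise ScreenError(
            f"sensor of {len(sensor)} nt shorter than index k={index.k}"
        )
    per_record: dict[str, int] = {}
    for query in (sensor.residues, reverse_complement(sensor).residues):
        for i in range(len(query) - index.k + 1):
            for rec_id, _pos in index.lookup(query[i : i + index.k]):
                if rec_id not in exclusions:
                    per_record[rec_id] = per_record.get(rec_id, 0) + 1
    return per_record


def rank_candidates(
    windows: Iterable[TriggerWindow], cfg: ScreenConfig | None = None
) -> list[TriggerWindow]:
    """Drop windows failing any hard filter; sort survivors deterministically.

    Order: |GC - 0.50| ascending, then fold score, then 5'-most start.
    """
    cfg = cfg or ScreenConfig()
    survivors = [w for w in windows if w.passes(cfg)]
    survivors.sort(key=TriggerWindow.rank_score)
    return survivors


def screen_trigger(
    trigger: NucleicSequence,
    cfg: ScreenConfig | None = None,
    background: Iterable[NucleicSequence] | None = None,
) -> tuple[list[TriggerWindow], list[TriggerWindow]]:
    """Full screen: enumerate, evaluate, rank. Returns (ranked, all evaluated)."""
    cfg = cfg or ScreenConfig()
    index = None
    if background is not None:
        index = build_kmer_index(background, cfg.offtarget_k)
    evaluated = [
        evaluate_window(w, cfg, index) for w in enumerate_windows(trigger, cfg)
    ]
    return rank_candidates(evaluated, cfg), evaluated


def windows_to_frame(
    windows: Iterable[TriggerWindow], cfg: ScreenConfig | None = None
) -> pd.DataFrame:
    """Tabular report of evaluated windows with pass flags and ranks."""
    cfg = cfg or ScreenConfig()
    ranked = rank_candidates([w for w in windows if w.evaluated], cfg)
    rank_of = {(w.source_id, w.start, w.length): i + 1 for i, w in enumerate(ranked)}
    rows = []
    for w in windows:
        rows.append(
            {
                "source_id": w.source_id,
                "start": w.start,
                "length": w.length,
                "window_seq": w.sequence.residues,
                "sensor_seq": w.sensor.residues if w.sensor else "",
                "gc": round(w.gc, 4) if w.gc is not None else None,
                "motif_hits": ";".join(f"{m}@{p}" for m, p in w.motif_hits),
                "fold_score": w.fold,
                "fold_ok": w.fold is not None and w.fold <= cfg.fold_ceiling,
                "offtarget_hits": w.offtarget_hits,
                "pass": w.evaluated and w.passes(cfg),
                "rank": rank_of.get((w.source_id, w.start, w.length), 0),
            }
        )
    return pd.DataFrame(rows)


def write_report(
    frame: pd.DataFrame, tsv_path: str | Path | None, json_path: str | Path | None
) -> None:
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(frame.to_dict(orient="records"), indent=2) + "\n"
        )
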