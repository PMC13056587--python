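"""Copy-number segment curation and genomic-complexity (GC) scoring.

Raw per-patient segment calls (SEG-style tables from arrays, methylation
arrays or shallow WGS) are turned into curated, countable copy-number
alteration (CNA) events:

* copy-number-neutral LOH is excluded from counting;
* same-direction segments within a configurable gap (default 5 Mb) merge
  into one event, as do oscillating chromothripsis-like clusters;
* events outside a catalog of recurrently altered regions must reach a
  minimum size (default 5 Mb) to be retained, while any overlap with a
  catalog region retains an event regardless of size;
* events covering most of a chromosome are reclassified as aneuploidies;
* biallelic losses count as two CNAs, everything else as one.

The resulting per-patient CNA count stratifies genomic complexity into
LGC (0-2), IGC (3-4) and HGC (>=5).
"""

from __future__ import annotations

import importlib.resources
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import (
    ConfigurationError,
    ContractViolation,
    ParseError,
    UndefinedResultError,
    ValidationError,
)

ALLOWED_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_ORDER = {c: i for i, c in enumerate(ALLOWED_CHROMS)}

MB = 1_000_000


class SegState(str, Enum):
    LOSS = "LOSS"
    BIALLELIC_LOSS = "BIALLELIC_LOSS"
    GAIN = "GAIN"
    CN_LOH = "CN_LOH"


class EventKind(str, Enum):
    LOSS = "LOSS"
    BIALLELIC_LOSS = "BIALLELIC_LOSS"
    GAIN = "GAIN"
    ANEUPLOIDY_GAIN = "ANEUPLOIDY_GAIN"
    ANEUPLOIDY_LOSS = "ANEUPLOIDY_LOSS"
    CHROMOTHRIPSIS_CLUSTER = "CHROMOTHRIPSIS_CLUSTER"


class GCClass(str, Enum):
    LGC = "LGC"
    IGC = "IGC"
    HGC = "HGC"


#: ordering used for monotonicity checks (LGC < IGC < HGC)
GC_ORDER = {GCClass.LGC: 0, GCClass.IGC: 1, GCClass.HGC: 2}

_LOSS_KINDS = frozenset(
    {EventKind.LOSS, EventKind.BIALLELIC_LOSS, EventKind.ANEUPLOIDY_LOSS}
)
_GAIN_KINDS = frozenset({EventKind.GAIN, EventKind.ANEUPLOIDY_GAIN})


def normalize_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix and validate against the allowed chromosome set."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c not in _CHROM_ORDER:
        raise ValidationError(f"unknown chromosome {chrom!r}")
    return c


@dataclass(frozen=True)
class Segment:
    """One raw copy-number interval, 0-based half-open coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: SegState
    platform: str = ""
    chromothripsis_flag: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "state", SegState(self.state))
        if self.end <= self.start:
            raise ValidationError(
                f"segment end must exceed start ({self.sample_id} "
                f"{self.chrom}:{self.start}-{self.end})"
            )

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CNAEvent:
    """A curated, countable CNA event.

    ``weight`` is the contribution to the per-patient CNA count: 2 for a
    biallelic loss, 1 for everything else.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    kind: EventKind
    region_hits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "kind", EventKind(self.kind))
        if self.end <= self.start:
            raise ValidationError("event end must exceed start")

    @property
    def weight(self) -> int:
        return 2 if self.kind is EventKind.BIALLELIC_LOSS else 1

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CurationParams:
    """Tunable thresholds of the curation rules (all in Mb except the
    chromothripsis switch count and the chromosome fraction)."""

    merge_gap_mb: float = 5.0
    min_size_mb: float = 5.0
    class13q_boundary_mb: float = 2.0
    aneuploidy_min_chrom_fraction: float = 0.9
    chromothripsis_min_switches: int = 10

    def __post_init__(self) -> None:
        for name in (
            "merge_gap_mb",
            "min_size_mb",
            "class13q_boundary_mb",
            "aneuploidy_min_chrom_fraction",
            "chromothripsis_min_switches",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class GCThresholds:
    lgc_max: int = 2
    igc_max: int = 4

    def __post_init__(self) -> None:
        if not self.lgc_max < self.igc_max:
            raise ValidationError("lgc_max must be below igc_max")


@dataclass(frozen=True)
class ConcordanceResult:
    locus: str
    n_compared: int
    n_agree: int

    @property
    def percent_agreement(self) -> float:
        return 100.0 * self.n_agree / self.n_compared


class RegionCatalog:
    """Named genomic regions retained regardless of size (recurrent arms and
    gene loci: TP53, ATM, BIRC3, RB1, 13q14 MDR)."""

    def __init__(
        self,
        regions: Sequence[tuple[str, str, int, int]],
        genome_build: str = "GRCh37",
    ) -> None:
        if not regions:
            raise ConfigurationError("region catalog is empty")
        names = [r[0] for r in regions]
        if len(set(names)) != len(names):
            raise ConfigurationError("region names must be unique")
        self.genome_build = genome_build
        self.regions = [
            (name, normalize_chrom(chrom), int(start), int(end))
            for name, chrom, start, end in regions
        ]
        for name, chrom, start, end in self.regions:
            if end <= start or start < 0:
                raise ConfigurationError(f"invalid coordinates for region {name}")
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for name, chrom, start, end in self.regions:
            self._trees[chrom].addi(start, end, name)

    @classmethod
    def from_bed(cls, path: str | Path, genome_build: str = "GRCh37") -> "RegionCatalog":
        regions = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 BED columns")
                chrom, start, end, name = parts[:4]
                regions.append((name, chrom, int(start), int(end)))
        return cls(regions, genome_build=genome_build)

    @classmethod
    def default(cls) -> "RegionCatalog":
        ref = importlib.resources.files("gcx.data") / "regions_grch37.bed"
        with importlib.resources.as_file(ref) as path:
            return cls.from_bed(path, genome_build="GRCh37")

    def names(self) -> list[str]:
        return [r[0] for r in self.regions]

    def overlapping(self, chrom: str, start: int, end: int) -> tuple[str, ...]:
        """Names of catalog regions overlapping [start, end) by >= 1 bp."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return ()
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return tuple(hits)


def load_chrom_lengths(path: str | Path | None = None) -> dict[str, int]:
    """Chromosome length table; the bundled default is GRCh37."""
    if path is None:
        ref = importlib.resources.files("gcx.data") / "chrom_lengths_grch37.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {normalize_chrom(r.chrom): int(r.length) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# Input parsing

_STATE_ALIASES = {
    "loss": SegState.LOSS,
    "del": SegState.LOSS,
    "deletion": SegState.LOSS,
    "biallelic_loss": SegState.BIALLELIC_LOSS,
    "biallelic": SegState.BIALLELIC_LOSS,
    "gain": SegState.GAIN,
    "amp": SegState.GAIN,
    "cn_loh": SegState.CN_LOH,
    "cnloh": SegState.CN_LOH,
    "loh": SegState.CN_LOH,
}


def _state_from_copy_number(cn: float) -> SegState | None:
    if cn == 0:
        return SegState.BIALLELIC_LOSS
    if cn == 1:
        return SegState.LOSS
    if cn == 2:
        return None  # copy-neutral row: not a CNA
    return SegState.GAIN


def read_seg(path: str | Path, dialect: str = "seg_1based") -> list[Segment]:
    """Read a SEG-style tab-delimited file into Segment records.

    ``dialect`` names the input coordinate convention: ``seg_1based``
    (1-based inclusive, the common SEG convention) or ``bed_0based``
    (0-based half-open). Internally everything is 0-based half-open.
    A ``state`` column is preferred; otherwise an integer ``copy_number``
    column is translated (0 biallelic loss, 1 loss, >=3 gain; 2 skipped).
    """
    if dialect not in ("seg_1based", "bed_0based"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    has_state = "state" in df.columns
    if not has_state and "copy_number" not in df.columns:
        raise ParseError(f"{path}: need a 'state' or 'copy_number' column")
    offset = 1 if dialect == "seg_1based" else 0
    segments: list[Segment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            if has_state:
                raw = str(getattr(row, "state")).strip().lower()
                if raw not in _STATE_ALIASES:
                    raise ValidationError(f"unknown state code {raw!r}")
                state = _STATE_ALIASES[raw]
            else:
                state = _state_from_copy_number(float(getattr(row, "copy_number")))
                if state is None:
                    continue
            flag = bool(getattr(row, "chromothripsis_flag", False))
            if pd.isna(flag):
                flag = False
            segments.append(
                Segment(
                    sample_id=str(row.sample),
                    chrom=str(row.chrom),
                    start=int(row.start) - offset,
                    end=int(row.end),
                    state=state,
                    platform=str(getattr(row, "platform", "")),
                    chromothripsis_flag=flag,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return segments


# ---------------------------------------------------------------------------
# Curation steps

def exclude_cn_neutral_loh(segments: Iterable[Segment]) -> list[Segment]:
    """Drop copy-number-neutral LOH segments; everything else passes through
    unchanged, order preserved."""
    return [s for s in segments if s.state is not SegState.CN_LOH]


def _direction(kind_or_state) -> str:
    if kind_or_state in (SegState.GAIN, EventKind.GAIN, EventKind.ANEUPLOIDY_GAIN):
        return "gain"
    return "loss"


def _single_sample(items) -> str:
    ids = {x.sample_id for x in items}
    if len(ids) > 1:
        raise ContractViolation(f"expected one sample, got {sorted(ids)}")
    return next(iter(ids))


def _chrom_key(chrom: str) -> int:
    return _CHROM_ORDER[chrom]


def _as_provisional_events(items: Sequence) -> list[CNAEvent]:
    events = []
    for x in items:
        if isinstance(x, CNAEvent):
            events.append(x)
        else:
            if x.state is SegState.CN_LOH:
                raise ContractViolation("CN-LOH segments must be excluded before merging")
            events.append(
                CNAEvent(
                    sample_id=x.sample_id,
                    chrom=x.chrom,
                    start=x.start,
                    end=x.end,
                    kind=EventKind(x.state.value),
                )
            )
    return events


def merge_proximal(
    items: Sequence[Segment] | Sequence[CNAEvent],
    params: CurationParams = CurationParams(),
) -> list[CNAEvent]:
    """Merge same-chromosome, same-direction events whose gap is within
    ``merge_gap_mb`` (inclusive) into one event spanning their union.

    Merging is transitive; a chain of events each within the gap of its
    neighbour collapses to a single event. Losses merge only with losses
    and gains only with gains. A merge involving a biallelic loss yields a
    biallelic loss (the double-hit is not forgotten). Aneuploidy and
    chromothripsis events pass through untouched. Accepts raw segments
    (CN-LOH already excluded) or previously merged events, so the
    operation is idempotent.
    """
    if not items:
        return []
    _single_sample(items)
    events = _as_provisional_events(items)
    _pass_kinds = (
        EventKind.ANEUPLOIDY_GAIN,
        EventKind.ANEUPLOIDY_LOSS,
        EventKind.CHROMOTHRIPSIS_CLUSTER,
    )
    passthrough = [e for e in events if e.kind in _pass_kinds]
    mergeable = [e for e in events if e.kind not in _pass_kinds]
    gap_bp = params.merge_gap_mb * MB
    merged: list[CNAEvent] = []
    groups: dict[tuple[str, str], list[CNAEvent]] = defaultdict(list)
    for e in mergeable:
        groups[(e.chrom, _direction(e.kind))].append(e)
    for (chrom, direction), group in groups.items():
        group.sort(key=lambda e: (e.start, e.end))
        cur_start, cur_end = group[0].start, group[0].end
        cur_biallelic = group[0].kind is EventKind.BIALLELIC_LOSS
        sample = group[0].sample_id

        def flush() -> None:
            kind = (
                EventKind.BIALLELIC_LOSS
                if cur_biallelic
                else (EventKind.GAIN if direction == "gain" else EventKind.LOSS)
            )
            merged.append(
                CNAEvent(sample_id=sample, chrom=chrom, start=cur_start, end=cur_end, kind=kind)
            )

        for e in group[1:]:
            if e.start - cur_end <= gap_bp:
                cur_end = max(cur_end, e.end)
                cur_biallelic = cur_biallelic or e.kind is EventKind.BIALLELIC_LOSS
            else:
                flush()
                cur_start, cur_end = e.start, e.end
                cur_biallelic = e.kind is EventKind.BIALLELIC_LOSS
        flush()
    out = merged + passthrough
    out.sort(key=lambda e: (_chrom_key(e.chrom), e.start, e.end))
    return out


def detect_chromothripsis(
    segments: Sequence[Segment],
    params: CurationParams = CurationParams(),
) -> tuple[list[CNAEvent], list[Segment]]:
    """Collapse chromothripsis-like oscillation into single cluster events.

    Returns ``(cluster_events, remaining_segments)``. Two routes flag a
    chromosome: an explicit per-segment ``chromothripsis_flag`` (the flagged
    segments collapse to one cluster, unflagged neighbours survive), or an
    oscillation heuristic — walking the chromosome's segments in order and
    inserting an implied copy-neutral state into every gap, at least
    ``chromothripsis_min_switches`` adjacent state changes collapse the whole
    chromosome. Each cluster contributes weight 1 to the CNA count.
    """
    if not segments:
        return [], []
    _single_sample(segments)
    clusters: list[CNAEvent] = []
    remaining: list[Segment] = []
    by_chrom: dict[str, list[Segment]] = defaultdict(list)
    for s in segments:
        by_chrom[s.chrom].append(s)
    for chrom in sorted(by_chrom, key=_chrom_key):
        segs = sorted(by_chrom[chrom], key=lambda s: (s.start, s.end))
        flagged = [s for s in segs if s.chromothripsis_flag]
        unflagged = [s for s in segs if not s.chromothripsis_flag]
        if flagged:
            clusters.append(
                CNAEvent(
                    sample_id=flagged[0].sample_id,
                    chrom=chrom,
                    start=min(s.start for s in flagged),
                    end=max(s.end for s in flagged),
                    kind=EventKind.CHROMOTHRIPSIS_CLUSTER,
                )
            )
            segs = unflagged
        if len(segs) >= 2:
            walk: list[str] = []
            prev_end = None
            for s in segs:
                if prev_end is not None and s.start > prev_end:
                    walk.append("NEUTRAL")
                walk.append(s.state.value)
                prev_end = s.end if prev_end is None else max(prev_end, s.end)
            switches = sum(1 for a, b in zip(walk, walk[1:]) if a != b)
            if switches >= params.chromothripsis_min_switches:
                clusters.append(
                    CNAEvent(
                        sample_id=segs[0].sample_id,
                        chrom=chrom,
                        start=min(s.start for s in segs),
                        end=max(s.end for s in segs),
                        kind=EventKind.CHROMOTHRIPSIS_CLUSTER,
                    )
                )
                segs = []
        remaining.extend(segs)
    remaining.sort(key=lambda s: (_chrom_key(s.chrom), s.start, s.end))
    return clusters, remaining


def apply_size_and_region_filter(
    events: Sequence[CNAEvent],
    catalog: RegionCatalog,
    params: CurationParams = CurationParams(),
) -> list[CNAEvent]:
    """Retain an event iff it overlaps a catalog region by >= 1 bp or its
    size reaches ``min_size_mb`` (inclusive). Chromothripsis clusters are
    curated events by definition and always retained. ``region_hits`` is
    populated on every retained event."""
    if catalog is None or not catalog.regions:
        raise ConfigurationError("a non-empty region catalog is required")
    min_bp = params.min_size_mb * MB
    retained = []
    for e in events:
        hits = catalog.overlapping(e.chrom, e.start, e.end)
        if hits or e.size_bp >= min_bp or e.kind is EventKind.CHROMOTHRIPSIS_CLUSTER:
            retained.append(replace(e, region_hits=hits))
    return retained


def detect_aneuploidy(
    events: Sequence[CNAEvent],
    chrom_lengths: Mapping[str, int],
    params: CurationParams = CurationParams(),
) -> list[CNAEvent]:
    """Reclassify events covering >= ``aneuploidy_min_chrom_fraction`` of
    their chromosome as whole-chromosome gains/losses (e.g. trisomy 12).
    Biallelic losses keep their kind (and weight 2)."""
    out = []
    for e in events:
        if e.kind in (EventKind.LOSS, EventKind.GAIN):
            length = chrom_lengths.get(e.chrom)
            if length is None:
                raise ConfigurationError(f"no chromosome length for {e.chrom!r}")
            if e.size_bp >= params.aneuploidy_min_chrom_fraction * length:
                kind = (
                    EventKind.ANEUPLOIDY_GAIN
                    if e.kind is EventKind.GAIN
                    else EventKind.ANEUPLOIDY_LOSS
                )
                e = replace(e, kind=kind)
        out.append(e)
    return out


def count_cna(events: Iterable[CNAEvent]) -> int:
    """Per-sample CNA count: sum of event weights (biallelic loss = 2)."""
    return sum(e.weight for e in events)


def classify_gc(count: int, thresholds: GCThresholds = GCThresholds()) -> GCClass:
    """Genomic-complexity class from the CNA count: LGC 0-2, IGC 3-4, HGC >=5
    under the default thresholds."""
    if count < 0:
        raise ValidationError("CNA count cannot be negative")
    if count <= thresholds.lgc_max:
        return GCClass.LGC
    if count <= thresholds.igc_max:
        return GCClass.IGC
    return GCClass.HGC


_REQUIRED_LOCI = ("TP53", "ATM", "BIRC3", "13q14_MDR")


def call_canonical_lesions(
    events: Sequence[CNAEvent], catalog: RegionCatalog
) -> dict[str, bool]:
    """Per-sample canonical CLL lesion flags from curated events.

    del17p/del11q/birc3_del: a loss overlapping TP53/ATM/BIRC3; del13q via
    the 13q14 minimally deleted region (monoallelic and biallelic reported
    separately); tri12: a whole-chromosome-12 gain.
    """
    missing = [l for l in _REQUIRED_LOCI if l not in set(catalog.names())]
    if missing:
        raise ConfigurationError(f"catalog lacks required loci: {missing}")
    flags = {
        "del17p": False,
        "del11q": False,
        "del13q_mono": False,
        "del13q_biallelic": False,
        "tri12": False,
        "birc3_del": False,
    }
    for e in events:
        if e.kind is EventKind.ANEUPLOIDY_GAIN and e.chrom == "12":
            flags["tri12"] = True
        if e.kind not in _LOSS_KINDS:
            continue
        hits = set(e.region_hits) or set(catalog.overlapping(e.chrom, e.start, e.end))
        if "TP53" in hits:
            flags["del17p"] = True
        if "ATM" in hits:
            flags["del11q"] = True
        if "BIRC3" in hits:
            flags["birc3_del"] = True
        if "13q14_MDR" in hits:
            if e.kind is EventKind.BIALLELIC_LOSS:
                flags["del13q_biallelic"] = True
            else:
                flags["del13q_mono"] = True
    return flags


def classify_del13q_size(
    event: CNAEvent, params: CurationParams = CurationParams()
) -> str:
    """13q deletion size class: Class I up to the 2 Mb boundary (inclusive),
    Class II above it. Larger (Class II) deletions track with complexity."""
    if event.chrom != "13" or event.kind not in _LOSS_KINDS:
        raise ContractViolation("classify_del13q_size expects a 13q loss event")
    boundary = params.class13q_boundary_mb * MB
    return "ClassI" if event.size_bp <= boundary else "ClassII"


def fish_concordance(
    genomic_calls: Mapping[str, bool | None],
    fish_calls: Mapping[str, bool | None],
    locus: str,
) -> ConcordanceResult:
    """Percentage agreement between genomic and FISH lesion calls.

    Samples missing either call are excluded from the denominator.
    """
    compared = [
        s
        for s in genomic_calls
        if genomic_calls.get(s) is not None and fish_calls.get(s) is not None
    ]
    if not compared:
        raise UndefinedResultError(f"no comparable samples for {locus}")
    agree = sum(1 for s in compared if bool(genomic_calls[s]) == bool(fish_calls[s]))
    return ConcordanceResult(locus=locus, n_compared=len(compared), n_agree=agree)


# ---------------------------------------------------------------------------
# Whole-sample / whole-cohort pipeline

def curate_sample(
    segments: Sequence[Segment],
    catalog: RegionCatalog,
    chrom_lengths: Mapping[str, int],
    params: CurationParams = CurationParams(),
    thresholds: GCThresholds = GCThresholds(),
) -> tuple[list[CNAEvent], dict]:
    """Run the full curation chain for one sample.

    Order: exclude CN-LOH -> collapse chromothripsis -> merge proximal ->
    size/region filter -> aneuploidy reclassification. Returns the curated
    events and a summary dict (cna_count, gc_class, lesion flags, 13q size
    class of the largest 13q deletion if any).
    """
    segs = exclude_cn_neutral_loh(segments)
    clusters, segs = detect_chromothripsis(segs, params)
    events = merge_proximal(list(segs) + list(clusters), params) if (segs or clusters) else []
    events = apply_size_and_region_filter(events, catalog, params)
    events = detect_aneuploidy(events, chrom_lengths, params)
    count = count_cna(events)
    flags = call_canonical_lesions(events, catalog)
    del13q_events = [
        e
        for e in events
        if e.chrom == "13" and e.kind in _LOSS_KINDS and "13q14_MDR" in e.region_hits
    ]
    del13q_class = None
    if del13q_events:
        largest = max(del13q_events, key=lambda e: e.size_bp)
        del13q_class = classify_del13q_size(largest, params)
    summary = {
        "cna_count": count,
        "gc_class": classify_gc(count, thresholds).value,
        "del13q_class": del13q_class,
        **flags,
    }
    return events, summary


def curate_cohort(
    segments: Sequence[Segment],
    catalog: RegionCatalog | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    params: CurationParams = CurationParams(),
    thresholds: GCThresholds = GCThresholds(),
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[CNAEvent], pd.DataFrame]:
    """Curate a multi-sample segment collection.

    ``sample_ids`` may list samples with no segments at all (CNA count 0);
    by default only samples present in ``segments`` are reported. Returns
    (all curated events, per-sample summary DataFrame indexed by sample_id).
    """
    if catalog is None:
        catalog = RegionCatalog.default()
    if chrom_lengths is None:
        chrom_lengths = load_chrom_lengths()
    by_sample: dict[str, list[Segment]] = defaultdict(list)
    for s in segments:
        by_sample[s.sample_id].append(s)
    ids = list(sample_ids) if sample_ids is not None else sorted(by_sample)
    all_events: list[CNAEvent] = []
    rows = []
    for sid in ids:
        events, summary = curate_sample(
            by_sample.get(sid, []), catalog, chrom_lengths, params, thresholds
        )
        all_events.extend(events)
        rows.append({"sample_id": sid, **summary})
    summary_df = pd.DataFrame(rows).set_index("sample_id")
    return all_events, summary_df


def events_to_frame(events: Sequence[CNAEvent]) -> pd.DataFrame:
    """Tabular view of curated events (one row per event)."""
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "kind": e.kind.value,
                "weight": e.weight,
                "size_bp": e.size_bp,
                "region_hits": ",".join(e.region_hits),
            }
            for e in events
        ],
        columns=[
            "sample_id",
            "chrom",
            "start",
            "end",
            "kind",
            "weight",
            "size_bp",
            "region_hits",
        ],
    )
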