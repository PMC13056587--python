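import numpy as np
import pytest

from gcx.segments import (
    MB,
    CNAEvent,
    CurationParams,
    EventKind,
    RegionCatalog,
    Segment,
    SegState,
    load_chrom_lengths,
)


@pytest.fixture(scope="session")
def catalog():
    return RegionCatalog.default()


@pytest.fixture(scope="session")
def chrom_lengths():
    return load_chrom_lengths()


def random_segments(rng, n, sample_id="S1", chroms=("1", "9", "13", "17")):
    """Random small segments (never large enough to trip the aneuploidy
    rule), including biallelic losses."""
    segs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, 100 * MB))
        size = int(rng.integers(100_000, 30 * MB))
        state = [SegState.LOSS, SegState.GAIN, SegState.BIALLELIC_LOSS][
            rng.integers(3)
        ]
        segs.append(
            Segment(sample_id=sample_id, chrom=chrom, start=start, end=start + size, state=state)
        )
    return segs


def brute_force_merge_filter(segments, catalog, params: CurationParams):
    """Independent oracle: transitive-closure merge by union-find over all
    pairwise gaps, then the size-or-region retention rule.

    Returns a sorted list of (chrom, start, end, kind) and the CNA count.
    Deliberately implemented with different machinery from the production
    sweep-merge.
    """
    gap_bp = params.merge_gap_mb * MB
    items = list(segments)
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def direction(s):
        return "gain" if s.state is SegState.GAIN else "loss"

    for i in range(n):
        for j in range(i + 1, n):
            a, b = items[i], items[j]
            if a.chrom != b.chrom or direction(a) != direction(b):
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= gap_bp:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(items[i])
    events = []
    for members in groups.values():
        start = min(s.start for s in members)
        end = max(s.end for s in members)
        biallelic = any(s.state is SegState.BIALLELIC_LOSS for s in members)
        if direction(members[0]) == "gain":
            kind = EventKind.GAIN
        else:
            kind = EventKind.BIALLELIC_LOSS if biallelic else EventKind.LOSS
        hits = catalog.overlapping(members[0].chrom, start, end)
        if hits or (end - start) >= params.min_size_mb * MB:
            events.append((members[0].chrom, start, end, kind))
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    count = sum(2 if k is EventKind.BIALLELIC_LOSS else 1 for _, _, _, k in events)
    return events, count


@pytest.fixture(scope="session")
def merge_filter_oracle():
    return brute_force_merge_filter
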