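"""Indexed on-disk overlap store built by a bucket sort.

Overlap computation writes shards (PAF text plus a per-read count file);
the store build partitions reads into bucket ranges balanced by overlap
count, duplicates each overlap with roles swapped (A->B and B->A), sorts
each bucket independently, and concatenates them with a JSON sidecar index
mapping read -> (offset, count). All overlaps of a read are contiguous, so
`get_overlaps` is a single sequential slice. Building with 1 bucket or N
buckets yields byte-identical stores.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path

from .overlap import Overlap, read_paf, write_paf

_SORT_KEY = lambda o: (o.a_id, o.b_id, o.a_start, o.a_end, o.orient)  # noqa: E731


class OverlapStore:
    """Sequential access to all overlaps of any read.

    In-memory view over a sorted record list plus the read index; backed by
    a directory (`store.paf` + `index.json`) when built on disk.
    """

    def __init__(self, records: list[Overlap], index: dict[str, tuple[int, int]]):
        self._records = records
        self._index = index

    @property
    def records(self) -> list[Overlap]:
        return self._records

    @property
    def read_ids(self) -> list[str]:
        return list(self._index)

    def __len__(self) -> int:
        return len(self._records)

    def get(self, read_id: str) -> list[Overlap]:
        """All overlaps whose first read is `read_id`, in sorted order."""
        if read_id not in self._index:
            return []
        off, n = self._index[read_id]
        return self._records[off : off + n]

    # ------------------------------------------------------------- persistence

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_paf(d / "store.paf", self._records)
        (d / "index.json").write_text(
            json.dumps({r: list(v) for r, v in self._index.items()}, sort_keys=True)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "OverlapStore":
        d = Path(directory)
        records = read_paf(d / "store.paf")
        index = {r: tuple(v) for r, v in json.loads((d / "index.json").read_text()).items()}
        return cls(records, index)

    def replace_records(self, records: list[Overlap]) -> "OverlapStore":
        """Same reads, updated records (e.g. adjusted error rates)."""
        return build_store_from_overlaps(records, duplicate=False)


def _index_records(records: list[Overlap]) -> dict[str, tuple[int, int]]:
    index: dict[str, tuple[int, int]] = {}
    start = 0
    for i, rec in enumerate(records):
        if i and rec.a_id != records[i - 1].a_id:
            index[records[i - 1].a_id] = (start, i - start)
            start = i
    if records:
        index[records[-1].a_id] = (start, len(records) - start)
    return index


def build_store_from_overlaps(
    overlaps: list[Overlap],
    known_reads: set[str] | None = None,
    max_bucket_size: int = 0,
    duplicate: bool = True,
) -> OverlapStore:
    """Bucket-sorted store from overlap records.

    Each input overlap appears twice (roles swapped) unless `duplicate` is
    False (records already two-sided). `max_bucket_size` caps records per
    bucket; 0 means a single bucket. The result is independent of bucket
    count and input order.
    """
    if known_reads is not None:
        for o in overlaps:
            if o.a_id not in known_reads or o.b_id not in known_reads:
                raise ValueError(f"overlap references unknown read: {o.a_id} / {o.b_id}")
    two_sided: list[Overlap] = []
    for o in overlaps:
        two_sided.append(o)
        if duplicate:
            two_sided.append(o.flipped())

    counts = Counter(o.a_id for o in two_sided)
    reads_sorted = sorted(counts)
    # bucket read-ranges balanced by overlap count, capped at max_bucket_size
    cap = max_bucket_size if max_bucket_size > 0 else max(len(two_sided), 1)
    buckets: list[list[str]] = []
    cur: list[str] = []
    cur_n = 0
    for r in reads_sorted:
        if cur and cur_n + counts[r] > cap:
            buckets.append(cur)
            cur, cur_n = [], 0
        cur.append(r)
        cur_n += counts[r]
    if cur:
        buckets.append(cur)

    by_read: dict[str, list[Overlap]] = {}
    for o in two_sided:
        by_read.setdefault(o.a_id, []).append(o)

    records: list[Overlap] = []
    for bucket in buckets:  # independent jobs; sequential fallback is identical
        chunk: list[Overlap] = []
        for r in bucket:
            chunk.extend(by_read.get(r, []))
        chunk.sort(key=_SORT_KEY)
        records.extend(chunk)
    return OverlapStore(records, _index_records(records))


def build_store(
    overlap_files: list[str | Path],
    max_bucket_size: int = 0,
    known_reads: set[str] | None = None,
) -> OverlapStore:
    """Build the store from PAF shards written by parallel overlap jobs."""
    overlaps: list[Overlap] = []
    for f in overlap_files:
        overlaps.extend(read_paf(f))
    return build_store_from_overlaps(overlaps, known_reads, max_bucket_size)


def get_overlaps(store: OverlapStore, read_id: str) -> list[Overlap]:
    return store.get(read_id)
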