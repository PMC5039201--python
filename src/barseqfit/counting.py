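"""Turn Bar-seq FASTQ files into a strain × sample count matrix.

Three steps per read: demultiplex on the 6-nt multiplex index (exact match
by default), locate the 20-nt tag window by matching the up-/down-tag common
primer at its fixed layout position (≤2 mismatches), and assign the window
to the catalog tag with the fewest mismatches, accepting it when that
minimum is ≤2 and uniquely attained. Up- and down-tag counts are then summed
per strain.

The per-read assignment is specified as an exhaustive minimum-Hamming scan
over the catalog; :class:`TagIndex` implements an equivalent fast path
(chunk pigeonhole: any 20-mer within 2 mismatches of a tag shares one of
three exact substrings with it) plus a window cache, and is checked against
the plain scan by tests.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import (
    CountMatrix,
    DEFAULT_LAYOUT,
    LEDGER_COLUMNS,
    ReadLayout,
    UNASSIGNED_ROW,
    seq_to_codes,
)
from .simulate import tags_frame

UNASSIGNED_TAG = "unassigned_tag"
AMBIGUOUS_TAG = "ambiguous_tag"
UNASSIGNED_INDEX = "unassigned_index"
NO_PRIMER = "no_primer"

_UNASSIGNED = -1
_AMBIGUOUS = -2


def hamming_mismatches(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def demultiplex(read: str, samplesheet: pd.DataFrame,
                layout: ReadLayout = DEFAULT_LAYOUT,
                max_index_mismatch: int = 0) -> str:
    """Assign a read to a sample by its multiplex index window.

    Returns the sample_id, or ``"unassigned_index"`` when no index matches
    within ``max_index_mismatch`` or two indices tie at the minimum.
    """
    lo = layout.index_offset
    window = read[lo:lo + layout.index_length]
    if len(window) < layout.index_length:
        return UNASSIGNED_INDEX
    best, best_d, tie = None, layout.index_length + 1, False
    for sid, idx in zip(samplesheet["sample_id"], samplesheet["index"]):
        d = hamming_mismatches(window, idx)
        if d < best_d:
            best, best_d, tie = sid, d, False
        elif d == best_d:
            tie = True
    if best_d <= max_index_mismatch and not tie:
        return best
    return UNASSIGNED_INDEX


def locate_tag_window(read: str, layout: ReadLayout = DEFAULT_LAYOUT,
                      max_primer_mismatch: int = 2):
    """Find the 20-nt tag window by matching either common primer.

    Both primers are tried at their fixed position after the index; the one
    with fewer mismatches (each ≤ ``max_primer_mismatch``) decides whether
    the read carries an up- or a down-tag. Returns ``(window, kind)`` or
    ``None`` when neither primer matches, the two tie, or the read is too
    short for a full tag window.
    """
    off = layout.primer_offset
    d_up = d_dn = max_primer_mismatch + 1
    up = read[off:off + len(layout.up_common_primer)]
    if len(up) == len(layout.up_common_primer):
        d_up = hamming_mismatches(up, layout.up_common_primer)
    dn = read[off:off + len(layout.down_common_primer)]
    if len(dn) == len(layout.down_common_primer):
        d_dn = hamming_mismatches(dn, layout.down_common_primer)
    if d_up > max_primer_mismatch and d_dn > max_primer_mismatch:
        return None
    if d_up == d_dn:
        return None
    if d_up < d_dn:
        start, kind = layout.up_tag_start, "up"
    else:
        start, kind = layout.down_tag_start, "down"
    window = read[start:start + layout.tag_length]
    if len(window) < layout.tag_length:
        return None
    return window, kind


def assign_tag(window: str, catalog: pd.DataFrame, max_mismatch: int = 2):
    """Assign a 20-mer window to a catalog tag by exhaustive Hamming scan.

    Returns ``(strain_id, kind)`` for the unique minimum-mismatch tag when
    the minimum is ≤ ``max_mismatch``; ``"ambiguous_tag"`` when two tags tie
    at that minimum; ``"unassigned_tag"`` otherwise.
    """
    tags = tags_frame(catalog)
    if tags.empty:
        raise ValueError("empty catalog")
    codes = np.stack([seq_to_codes(s) for s in tags["seq"]])
    if len(window) != codes.shape[1]:
        raise ValueError(f"window length {len(window)} != tag length {codes.shape[1]}")
    d = (codes != seq_to_codes(window)).sum(axis=1)
    m = int(d.min())
    if m > max_mismatch:
        return UNASSIGNED_TAG
    hits = np.nonzero(d == m)[0]
    if hits.size > 1:
        return AMBIGUOUS_TAG
    row = tags.iloc[int(hits[0])]
    return row["strain_id"], row["kind"]


class TagIndex:
    """Mismatch-tolerant tag lookup, equivalent to the exhaustive scan.

    Splits each tag into ``max_mismatch + 1`` chunks; a window within
    ``max_mismatch`` of a tag must match at least one chunk exactly
    (pigeonhole), so the union of chunk-dictionary hits contains every tag
    within the threshold and minimum/tie semantics are preserved exactly.
    """

    def __init__(self, catalog: pd.DataFrame, max_mismatch: int = 2):
        tags = tags_frame(catalog)
        if tags.empty:
            raise ValueError("empty catalog")
        self.max_mismatch = max_mismatch
        self.tag_id = tags["tag_id"].to_numpy()
        self.strain_id = tags["strain_id"].to_numpy()
        self.kind = tags["kind"].to_numpy()
        self.codes = np.stack([seq_to_codes(s) for s in tags["seq"]])
        self.L = self.codes.shape[1]
        self.exact = {s.encode(): i for i, s in enumerate(tags["seq"])}
        k = max_mismatch + 1
        bounds = np.linspace(0, self.L, k + 1).astype(int)
        self.chunks = list(zip(bounds[:-1], bounds[1:]))
        self.chunk_maps: list[dict[bytes, list[int]]] = []
        seqs = tags["seq"].to_numpy()
        for lo, hi in self.chunks:
            m: dict[bytes, list[int]] = {}
            for i, s in enumerate(seqs):
                m.setdefault(s[lo:hi].encode(), []).append(i)
            self.chunk_maps.append(m)

    def assign(self, window: bytes) -> int:
        """Row index of the assigned tag, or _UNASSIGNED / _AMBIGUOUS."""
        hit = self.exact.get(window)
        if hit is not None:
            return hit
        cand: set[int] = set()
        for (lo, hi), cmap in zip(self.chunks, self.chunk_maps):
            cand.update(cmap.get(window[lo:hi], ()))
        if not cand:
            return _UNASSIGNED
        rows = np.fromiter(cand, dtype=np.int64)
        w = seq_to_codes(window)
        d = (self.codes[rows] != w).sum(axis=1)
        m = int(d.min())
        if m > self.max_mismatch:
            return _UNASSIGNED
        hits = rows[d == m]
        return int(hits[0]) if hits.size == 1 else _AMBIGUOUS

    def assign_all(self, window: bytes) -> list[int]:
        """All tag rows within max_mismatch of the window (multi-count mode)."""
        hit = self.exact.get(window)
        cand: set[int] = set()
        for (lo, hi), cmap in zip(self.chunks, self.chunk_maps):
            cand.update(cmap.get(window[lo:hi], ()))
        if hit is not None:
            cand.add(hit)
        if not cand:
            return []
        rows = np.fromiter(cand, dtype=np.int64)
        w = seq_to_codes(window)
        d = (self.codes[rows] != w).sum(axis=1)
        return [int(r) for r in rows[d <= self.max_mismatch]]


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_tags(fastq_paths, catalog: pd.DataFrame, samplesheet: pd.DataFrame,
               layout: ReadLayout = DEFAULT_LAYOUT, max_mismatch: int = 2,
               max_index_mismatch: int = 0, multi_count: bool = False) -> CountMatrix:
    """Count tag occurrences per sample across one or more FASTQ files.

    Applies demultiplex → locate_tag_window → assign_tag to every read and
    accumulates a per-tag CountMatrix whose ledger classifies each read as
    assigned / unassigned_index / unassigned_tag (including primer failures)
    / ambiguous_tag. With ``multi_count=True`` a read is counted once for
    every tag within the mismatch threshold (the permissive reading of the
    original counting rule) instead of requiring a unique best hit.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    index_map = {idx: sid for sid, idx in zip(samplesheet["sample_id"], samplesheet["index"])}
    if len(index_map) != len(samplesheet):
        raise ValueError("duplicate multiplex indices in sample sheet")
    samples = list(samplesheet["sample_id"])
    sample_pos = {s: j for j, s in enumerate(samples)}
    tindex = TagIndex(catalog, max_mismatch=max_mismatch)
    n_tags = len(tindex.tag_id)
    counts = np.zeros((n_tags, len(samples)), dtype=np.int64)
    ledger = np.zeros((len(samples) + 1, 4), dtype=np.int64)  # last row: (unassigned)
    A, UI, UT, AT = range(4)

    i0, i1 = layout.index_offset, layout.index_offset + layout.index_length
    off = layout.primer_offset
    up_primer, dn_primer = layout.up_common_primer, layout.down_common_primer
    u0, u1 = off, off + len(up_primer)
    d0, d1 = off, off + len(dn_primer)
    ut0, ut1 = layout.up_tag_start, layout.up_tag_start + layout.tag_length
    dt0, dt1 = layout.down_tag_start, layout.down_tag_start + layout.tag_length
    max_pm = 2

    window_cache: dict[bytes, object] = {}
    for path in fastq_paths:
        with _open_maybe_gzip(path) as fh:
            try:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    sid = index_map.get(seq[i0:i1])
                    if sid is None:
                        if max_index_mismatch > 0:
                            sid = demultiplex(seq, samplesheet, layout, max_index_mismatch)
                            if sid == UNASSIGNED_INDEX:
                                sid = None
                        if sid is None:
                            ledger[-1, UI] += 1
                            continue
                    col = sample_pos[sid]
                    # primer match: exact fast path, then counted mismatches
                    if seq[u0:u1] == up_primer:
                        window = seq[ut0:ut1]
                    elif seq[d0:d1] == dn_primer:
                        window = seq[dt0:dt1]
                    else:
                        loc = locate_tag_window(seq, layout, max_pm)
                        if loc is None:
                            ledger[col, UT] += 1
                            continue
                        window = loc[0]
                    if len(window) < layout.tag_length:
                        ledger[col, UT] += 1
                        continue
                    wb = window.encode()
                    res = window_cache.get(wb)
                    if res is None:
                        if multi_count:
                            res = tuple(tindex.assign_all(wb))
                        else:
                            res = tindex.assign(wb)
                        window_cache[wb] = res
                    if multi_count:
                        if res:
                            for r in res:
                                counts[r, col] += 1
                            ledger[col, A] += 1
                        else:
                            ledger[col, UT] += 1
                    elif res == _UNASSIGNED:
                        ledger[col, UT] += 1
                    elif res == _AMBIGUOUS:
                        ledger[col, AT] += 1
                    else:
                        counts[res, col] += 1
                        ledger[col, A] += 1
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc

    counts_df = pd.DataFrame(counts, index=pd.Index(tindex.tag_id, name="tag_id"),
                             columns=samples)
    ledger_df = pd.DataFrame(ledger, index=pd.Index(samples + [UNASSIGNED_ROW], name="sample_id"),
                             columns=LEDGER_COLUMNS)
    return CountMatrix(counts=counts_df, ledger=ledger_df)


def aggregate_strains(tag_matrix: CountMatrix, catalog: pd.DataFrame) -> CountMatrix:
    """Sum up- and down-tag counts into per-strain counts, per sample."""
    tags = tags_frame(catalog).set_index("tag_id")
    orphans = set(tag_matrix.counts.index) - set(tags.index)
    if orphans:
        raise ValueError(f"tag ids absent from catalog: {sorted(orphans)[:3]}")
    strain = tags.loc[tag_matrix.counts.index, "strain_id"]
    agg = tag_matrix.counts.groupby(strain.to_numpy(), sort=False).sum()
    agg = agg.reindex(catalog["strain_id"], fill_value=0)  # catalog order
    agg.index.name = "strain_id"
    return CountMatrix(counts=agg, ledger=tag_matrix.ledger.copy())
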