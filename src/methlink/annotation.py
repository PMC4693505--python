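"""Genomic annotation of array probes.

Coordinate conventions, applied uniformly:

* interval tracks (CpG islands, chromatin segmentation, TFBS clusters) and
  gene models are BED-style 0-based half-open ``[start, end)``;
* probe manifest positions are 1-based single-base (array convention);
* the single conversion ``pos0 = pos - 1`` happens in :func:`overlap_track`
  and the position helpers here, nowhere else.

Each probe receives: a set of gene-region labels (upstream windows, 5'UTR,
first exon, gene body, 3'UTR, downstream windows, or intergenic), exactly
one CpG-island relation (island / shore / shelf / open sea), one collapsed
chromatin category, and the set of transcription factors whose binding-site
clusters cover it.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "IntervalTrack",
    "GENE_REGION_LABELS",
    "CHROMATIN_CATEGORIES",
    "annotate_gene_regions",
    "annotate_cgi_relation",
    "collapse_chromatin_state",
    "overlap_track",
    "annotate_probes",
]

GENE_REGION_LABELS = (
    "10kb_5p",
    "1p5kb_5p",
    "TSS200",
    "UTR5",
    "first_exon",
    "gene_body",
    "UTR3",
    "1p5kb_3p",
    "10kb_3p",
    "intergenic",
)

#: 15-state chromatin segmentation collapsed into 8 functional categories.
_STATE_CATEGORY = {
    1: "promoter",
    2: "promoter",
    3: "poised_promoter",
    4: "enhancer",
    5: "enhancer",
    6: "enhancer",
    7: "enhancer",
    8: "insulator",
    9: "strong_transcription",
    10: "strong_transcription",
    11: "weak_transcription",
    12: "polycomb_repressed",
    13: "heterochromatin",
    14: "heterochromatin",
    15: "heterochromatin",
}

CHROMATIN_CATEGORIES = (
    "promoter",
    "poised_promoter",
    "enhancer",
    "insulator",
    "strong_transcription",
    "weak_transcription",
    "polycomb_repressed",
    "heterochromatin",
    "unannotated",
)


@dataclass(frozen=True)
class GeneModel:
    """One transcript model per gene, 0-based half-open spans.

    The TSS is the strand-appropriate transcript end: ``tx_start`` (0-based)
    for + strand, ``tx_end - 1`` for - strand; reported 1-based via
    :attr:`tss`.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    first_exon: tuple[int, int]
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid transcript span")
        for name, iv in (("first_exon", self.first_exon), ("utr5", self.utr5), ("utr3", self.utr3)):
            if iv is None:
                continue
            s, e = iv
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {self.gene_id}: {name} outside transcript span")

    @property
    def tss(self) -> int:
        """1-based position of the transcription start site."""
        return self.tx_start + 1 if self.strand == "+" else self.tx_end


class IntervalTrack:
    """Labelled genomic intervals with point-overlap queries.

    Entries are (chrom, start, end, label) in 0-based half-open coordinates.
    Unsorted input is sorted internally (logged).  Query cost is
    O(log n + hits) per position via a per-chromosome sweep index.
    """

    def __init__(self, entries: Iterable[tuple[str, int, int, str]], kind: str = "generic"):
        df = pd.DataFrame(list(entries), columns=["chrom", "start", "end", "label"])
        if len(df):
            if (df["start"] >= df["end"]).any():
                bad = df[df["start"] >= df["end"]].iloc[0]
                raise ValueError(
                    f"interval with start >= end: {bad.chrom}:{bad.start}-{bad.end}"
                )
            if not df.groupby("chrom", sort=False)["start"].apply(
                lambda s: s.is_monotonic_increasing
            ).all():
                logger.info("interval track (%s) was unsorted; sorting internally", kind)
            df = df.sort_values(["chrom", "start", "end", "label"], kind="mergesort")
            df = df.reset_index(drop=True)
        self.df = df
        self.kind = kind
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            labels = sub["label"].tolist()
            # running maximum of interval ends, for bounded back-scan
            maxend = np.maximum.accumulate(ends)
            self._index[chrom] = (starts, ends, labels, maxend)

    def __len__(self) -> int:
        return len(self.df)

    def query(self, chrom: str, pos0: int) -> list[str]:
        """Labels of all intervals whose [start, end) contains ``pos0``."""
        idx = self._index.get(chrom)
        if idx is None:
            return []
        starts, ends, labels, maxend = idx
        hi = int(np.searchsorted(starts, pos0, side="right"))
        hits = []
        for i in range(hi - 1, -1, -1):
            if maxend[i] <= pos0:
                break
            if ends[i] > pos0:
                hits.append(labels[i])
        hits.reverse()
        return hits

    def merged_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Overlap-merged intervals on one chromosome, sorted."""
        idx = self._index.get(chrom)
        if idx is None:
            return []
        starts, ends = idx[0], idx[1]
        merged: list[tuple[int, int]] = []
        for s, e in zip(starts, ends):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((int(s), int(e)))
        return merged


def collapse_chromatin_state(state: int) -> str:
    """Map a 15-state segmentation label to one of 8 functional categories."""
    try:
        state = int(state)
    except (TypeError, ValueError):
        raise ValueError(f"chromatin state must be an integer, got {state!r}") from None
    if state not in _STATE_CATEGORY:
        raise ValueError(f"chromatin state {state} outside 1..15")
    return _STATE_CATEGORY[state]


def overlap_track(pos: int, chrom: str, track: IntervalTrack) -> list[str]:
    """All track labels overlapping a 1-based probe position."""
    return track.query(chrom, pos - 1)


def _regions_for_gene(pos: int, gene: GeneModel) -> set[str]:
    """Gene-region labels a 1-based position receives from one gene."""
    labels: set[str] = set()
    pos0 = pos - 1
    tss = gene.tss  # 1-based

    if gene.strand == "+":
        upstream = tss - pos  # bases 5' of the TSS, >= 1 when upstream
        three_prime_end = gene.tx_end  # 1-based last transcribed base
        downstream = pos - three_prime_end
    else:
        upstream = pos - tss
        three_prime_end = gene.tx_start + 1
        downstream = three_prime_end - pos

    if 1 <= upstream <= 200:
        labels.add("TSS200")
    elif 201 <= upstream <= 1500:
        labels.add("1p5kb_5p")
    elif 1501 <= upstream <= 10000:
        labels.add("10kb_5p")

    if gene.tx_start <= pos0 < gene.tx_end:
        fs, fe = gene.first_exon
        if gene.utr5 and gene.utr5[0] <= pos0 < gene.utr5[1]:
            labels.add("UTR5")
        if fs <= pos0 < fe:
            labels.add("first_exon")
        if gene.utr3 and gene.utr3[0] <= pos0 < gene.utr3[1]:
            labels.add("UTR3")
        # body: first intron through the last exon (3'-ward of the first exon)
        in_body = (pos0 >= fe) if gene.strand == "+" else (pos0 < fs)
        if in_body:
            labels.add("gene_body")

    if 1 <= downstream <= 1500:
        labels.add("1p5kb_3p")
    elif 1501 <= downstream <= 10000:
        labels.add("10kb_3p")

    return labels


def annotate_gene_regions(
    pos: int, chrom: str, genes: Sequence[GeneModel]
) -> tuple[set[str], set[str]]:
    """Gene-region labels and contributing gene ids for a 1-based position.

    The union runs over every gene whose +/-10 kb extended span contains the
    probe; an empty union yields ``{"intergenic"}``.
    """
    labels: set[str] = set()
    gene_ids: set[str] = set()
    pos0 = pos - 1
    for gene in genes:
        if gene.chrom != chrom:
            continue
        if not (gene.tx_start - 10000 <= pos0 < gene.tx_end + 10000):
            continue
        got = _regions_for_gene(pos, gene)
        if got:
            labels |= got
            gene_ids.add(gene.gene_id)
    if not labels:
        labels = {"intergenic"}
    return labels, gene_ids


def annotate_cgi_relation(pos: int, chrom: str, cgi: IntervalTrack) -> str:
    """Relation of a 1-based position to the CpG-island track.

    Inside an island -> ``island``; else by distance d (bp) to the nearest
    island edge: d in [1, 2000] -> ``shore``, [2001, 4000] -> ``shelf``,
    beyond -> ``open_sea``.
    """
    pos0 = pos - 1
    merged = cgi.merged_intervals(chrom)
    if not merged:
        return "open_sea"
    starts = [s for s, _ in merged]
    i = bisect_right(starts, pos0) - 1
    dist = None
    if i >= 0:
        s, e = merged[i]
        if pos0 < e:
            return "island"
        dist = pos0 - e + 1  # gap bases between island end and probe
    if i + 1 < len(merged):
        gap = merged[i + 1][0] - pos0
        dist = gap if dist is None else min(dist, gap)
    if dist <= 2000:
        return "shore"
    if dist <= 4000:
        return "shelf"
    return "open_sea"


def _chromatin_category(pos: int, chrom: str, chromatin: IntervalTrack | None) -> str:
    if chromatin is None:
        return "unannotated"
    labels = overlap_track(pos, chrom, chromatin)
    if not labels:
        return "unannotated"
    # BED label may be "5" or "E5"
    state = labels[0]
    state = int(str(state).lstrip("E"))
    return collapse_chromatin_state(state)


def annotate_probes(
    manifest: pd.DataFrame,
    genes: Sequence[GeneModel],
    cgi: IntervalTrack | None = None,
    chromatin: IntervalTrack | None = None,
    tfbs: IntervalTrack | None = None,
) -> pd.DataFrame:
    """Annotate every manifest probe against all supplied resources.

    ``manifest`` must carry ``chrom`` and ``pos`` (1-based) indexed by probe
    id.  Returns a DataFrame indexed by probe id with object columns
    ``gene_region_labels``, ``gene_ids``, ``tf_overlaps`` (frozensets) and
    string columns ``cgi_relation``, ``chromatin_category``.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for probe_id, row in manifest.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        labels, gene_ids = annotate_gene_regions(pos, chrom, by_chrom.get(chrom, []))
        cgi_rel = annotate_cgi_relation(pos, chrom, cgi) if cgi is not None else "open_sea"
        chrom_cat = _chromatin_category(pos, chrom, chromatin)
        tf = frozenset(overlap_track(pos, chrom, tfbs)) if tfbs is not None else frozenset()
        rows.append(
            (probe_id, frozenset(labels), frozenset(gene_ids), cgi_rel, chrom_cat, tf)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "gene_region_labels",
            "gene_ids",
            "cgi_relation",
            "chromatin_category",
            "tf_overlaps",
        ],
    ).set_index("probe_id")
    return out
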