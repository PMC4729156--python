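"""Gene models, GTF I/O, counting-bin construction, and catalog editing.

The central substrate of the benchmark is an annotation catalog
(genes -> transcripts -> exon intervals).  From it we derive the
counting-bin representations whose behaviour under a bin-vs-rest
differential-usage test is being compared:

* ``flatten``          -- disjoint sub-exonic bins, cut at every exon
                          boundary, with three ways of handling genes
                          whose exons overlap (aggregate into a complex,
                          exclude same-strand overlap, exclude overlap on
                          either strand);
* ``exon_bins``        -- the original (possibly overlapping) exons;
* ``junction_set``     -- splice junctions, counted from
                          junction-spanning fragments only;
* ``transcript_bins``  -- the isoforms themselves (quantified by an
                          equivalence-class EM in :mod:`dtubench.counting`).

Two catalog-editing operations complete the module: isoform prefiltering
(dropping isoforms whose relative abundance never exceeds a threshold,
the FDR-improving step this benchmark studies) and annotation degradation
(random removal of a fraction of transcripts to emulate an incomplete
catalog).

Coordinates are 0-based half-open internally; GTF I/O converts to and
from the 1-based inclusive convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Transcript:
    """An isoform: an ordered chain of non-overlapping exons."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chrom, strand = self.exons[0].chrom, self.exons[0].strand
        for a, b in zip(self.exons, self.exons[1:]):
            if b.chrom != chrom or b.strand != strand:
                raise ValueError(
                    f"transcript {self.transcript_id} mixes chromosomes/strands"
                )
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        """Spliced (mature) length in bp."""
        return sum(len(e) for e in self.exons)

    def junctions(self) -> list[tuple[int, int]]:
        """(donor end, acceptor start) pairs between consecutive exons."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]

    def exon_tuple(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)


@dataclass
class Gene:
    gene_id: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"transcript {t.transcript_id} carries gene_id {t.gene_id}, "
                    f"expected {self.gene_id}"
                )
        chrom, strand = self.transcripts[0].chrom, self.transcripts[0].strand
        for t in self.transcripts:
            if t.chrom != chrom or t.strand != strand:
                raise ValueError(f"gene {self.gene_id} mixes chromosomes/strands")
        self.transcripts = sorted(self.transcripts, key=lambda t: t.transcript_id)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged union of all exons, as sorted (start, end) pairs."""
        return merge_intervals(
            [(e.start, e.end) for t in self.transcripts for e in t.exons]
        )


@dataclass
class Annotation:
    """A catalog of genes with unique gene and transcript identifiers."""

    genes: list[Gene]
    provenance: str = ""

    def __post_init__(self) -> None:
        gids = [g.gene_id for g in self.genes]
        if len(set(gids)) != len(gids):
            raise ValueError("duplicate gene_ids in annotation")
        tids = [t.transcript_id for g in self.genes for t in g.transcripts]
        if len(set(tids)) != len(tids):
            raise ValueError("duplicate transcript_ids in annotation")
        self.genes = sorted(self.genes, key=lambda g: g.gene_id)

    def transcripts(self) -> dict[str, Transcript]:
        return {
            t.transcript_id: t for g in self.genes for t in g.transcripts
        }

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


BIN_TYPES = ("flat", "exon", "junction", "transcript")
OVERLAP_MODES = ("aggregate", "exclude_same_strand", "exclude_both_strands", "n/a")


@dataclass
class CountingBin:
    """One counting unit: a set of intervals owned by a feature.

    A junction bin stores its two 1-bp flanking anchors; a transcript bin
    stores the transcript's exons; flat and exon bins store one interval.
    """

    bin_id: str
    feature_id: str
    intervals: list[GenomicInterval]
    bin_type: str
    member_transcripts: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.bin_type not in BIN_TYPES:
            raise ValueError(f"unknown bin_type {self.bin_type!r}")
        if not self.intervals:
            raise ValueError(f"bin {self.bin_id} has no intervals")
        self.intervals = sorted(self.intervals, key=lambda e: e.start)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise ValueError(f"bin {self.bin_id} has overlapping intervals")


@dataclass
class BinSet:
    bins: list[CountingBin]
    overlap_mode: str = "n/a"
    complex_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.overlap_mode not in OVERLAP_MODES:
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")
        ids = [b.bin_id for b in self.bins]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate bin_ids in BinSet")
        for b in self.bins:
            if b.feature_id not in self.complex_map:
                self.complex_map[b.feature_id] = {b.feature_id}

    @property
    def bin_type(self) -> str:
        return self.bins[0].bin_type if self.bins else "flat"

    def feature_ids(self) -> list[str]:
        return [b.feature_id for b in self.bins]


# ---------------------------------------------------------------------------
# Interval helpers
# ---------------------------------------------------------------------------

def merge_intervals(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended (start, end) pairs."""
    if not pairs:
        return []
    pairs = sorted(pairs)
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(p) for p in merged]


def _subtract(pairs: list[tuple[int, int]], forbidden: list[tuple[int, int]]):
    """Set-subtract merged `forbidden` intervals from merged `pairs`."""
    out = []
    for s, e in pairs:
        cur = s
        for fs, fe in forbidden:
            if fe <= cur or fs >= e:
                continue
            if fs > cur:
                out.append((cur, fs))
            cur = max(cur, fe)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def read_gtf(path) -> Annotation:
    """Read exon features from a GTF file into an :class:`Annotation`.

    1-based inclusive GTF coordinates become 0-based half-open.  Bookended
    duplicate exons within a transcript are merged.  Raises ``ValueError``
    with the offending line number for malformed rows, and rejects exon
    rows lacking a ``transcript_id`` attribute.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    by_tx: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        if "transcript_id" not in feat.attributes:
            raise ValueError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks transcript_id"
            )
        if "gene_id" not in feat.attributes:
            raise ValueError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks gene_id"
            )
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        tx_gene.setdefault(tid, gid)
        by_tx.setdefault(tid, []).append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    genes: dict[str, list[Transcript]] = {}
    for tid, exons in by_tx.items():
        merged = merge_intervals([(e.start, e.end) for e in exons])
        chrom, strand = exons[0].chrom, exons[0].strand
        tx = Transcript(
            tid,
            tx_gene[tid],
            [GenomicInterval(chrom, s, e, strand) for s, e in merged],
        )
        genes.setdefault(tx_gene[tid], []).append(tx)
    return Annotation(
        [Gene(gid, txs) for gid, txs in genes.items()], provenance=str(path)
    )


def write_gtf(ann: Annotation, path) -> None:
    """Write one GTF exon row per exon, 1-based inclusive, sorted by
    (gene_id, transcript_id, exon start)."""
    with open(path, "w") as fh:
        for gene in sorted(ann.genes, key=lambda g: g.gene_id):
            for tx in sorted(gene.transcripts, key=lambda t: t.transcript_id):
                for e in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                e.chrom,
                                "dtubench",
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                e.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def write_binset_bed(binset: BinSet, path) -> None:
    """BED6 export: one row per bin interval (name=bin_id, score=0)."""
    with open(path, "w") as fh:
        for b in binset.bins:
            for iv in b.intervals:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{b.bin_id}\t0\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# Flattening into disjoint bins
# ---------------------------------------------------------------------------

def _gene_groups(ann: Annotation, overlap_mode: str):
    """Partition genes into features.

    In aggregate mode, genes whose exon unions overlap by >=1 bp on the
    same strand are merged transitively into a complex whose feature_id is
    the sorted gene ids joined with '+'.  In the exclusion modes every
    gene is its own feature.
    """
    if overlap_mode != "aggregate":
        return [
            (g.gene_id, [g]) for g in sorted(ann.genes, key=lambda g: g.gene_id)
        ]
    # union-find over same-strand exon-union overlap
    genes = sorted(ann.genes, key=lambda g: g.gene_id)
    parent = list(range(len(genes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    unions = [g.exon_union() for g in genes]
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            gi, gj = genes[i], genes[j]
            if gi.chrom != gj.chrom or gi.strand != gj.strand:
                continue
            if any(
                s1 < e2 and s2 < e1
                for s1, e1 in unions[i]
                for s2, e2 in unions[j]
            ):
                union(i, j)
    groups: dict[int, list[Gene]] = {}
    for i, g in enumerate(genes):
        groups.setdefault(find(i), []).append(g)
    out = []
    for members in groups.values():
        fid = "+".join(sorted(g.gene_id for g in members))
        out.append((fid, members))
    return sorted(out)


def _forbidden_regions(ann: Annotation, overlap_mode: str):
    """Sub-intervals covered by the exon unions of >=2 genes.

    Keyed by (chrom, strand) for exclude_same_strand and by chrom alone
    for exclude_both_strands (strand is ignored when detecting sharing).
    """
    events: dict = {}
    for g in ann.genes:
        key = (g.chrom, g.strand) if overlap_mode == "exclude_same_strand" else g.chrom
        for s, e in g.exon_union():
            events.setdefault(key, []).append((s, 1))
            events.setdefault(key, []).append((e, -1))
    forbidden: dict = {}
    for key, evs in events.items():
        evs.sort()
        depth, prev = 0, None
        regions = []
        for pos, delta in evs:
            if prev is not None and pos > prev and depth >= 2:
                regions.append((prev, pos))
            depth += delta
            prev = pos
        forbidden[key] = merge_intervals(regions)
    return forbidden


def flatten(ann: Annotation, overlap_mode: str = "aggregate") -> BinSet:
    """Cut exon unions at every exon boundary into disjoint flat bins.

    Within each feature, bins are the maximal runs of bases covered by an
    identical set of transcripts.  ``overlap_mode`` controls genes with
    overlapping exons: ``aggregate`` merges them into a '+'-joined
    complex; ``exclude_same_strand`` / ``exclude_both_strands`` drop the
    shared sub-intervals from every gene involved (considering genes on
    the same strand only, or on either strand, respectively).
    """
    if overlap_mode not in ("aggregate", "exclude_same_strand", "exclude_both_strands"):
        raise ValueError(f"invalid overlap_mode {overlap_mode!r}")
    forbidden = (
        _forbidden_regions(ann, overlap_mode)
        if overlap_mode != "aggregate"
        else {}
    )
    bins: list[CountingBin] = []
    complex_map: dict[str, set[str]] = {}
    for fid, members in _gene_groups(ann, overlap_mode):
        complex_map[fid] = {g.gene_id for g in members}
        txs = [t for g in members for t in g.transcripts]
        chrom = members[0].chrom
        boundaries = sorted(
            {pos for t in txs for e in t.exons for pos in (e.start, e.end)}
        )
        if overlap_mode != "aggregate":
            key = (
                (chrom, members[0].strand)
                if overlap_mode == "exclude_same_strand"
                else chrom
            )
            fb = forbidden.get(key, [])
            boundaries = sorted(
                set(boundaries)
                | {p for s, e in fb for p in (s, e)}
            )
        else:
            fb = []
        # label each elementary segment with its covering-transcript set
        segs = []
        for s, e in zip(boundaries, boundaries[1:]):
            cover = frozenset(
                t.transcript_id
                for t in txs
                if any(ex.start <= s and e <= ex.end for ex in t.exons)
            )
            if not cover:
                continue
            if fb and any(fs <= s and e <= fe for fs, fe in fb):
                continue
            segs.append((s, e, cover))
        # merge contiguous segments with identical covering sets
        runs = []
        for s, e, cover in segs:
            if runs and runs[-1][1] == s and runs[-1][2] == cover:
                runs[-1][1] = e
            else:
                runs.append([s, e, cover])
        strand = members[0].strand
        for k, (s, e, cover) in enumerate(runs, start=1):
            bins.append(
                CountingBin(
                    bin_id=f"{fid}:{k:03d}",
                    feature_id=fid,
                    intervals=[GenomicInterval(chrom, s, e, strand)],
                    bin_type="flat",
                    member_transcripts=set(cover),
                )
            )
    return BinSet(bins, overlap_mode=overlap_mode, complex_map=complex_map)


# ---------------------------------------------------------------------------
# Alternative bin definitions
# ---------------------------------------------------------------------------

def exon_bins(ann: Annotation) -> BinSet:
    """One bin per distinct exon per gene; bins may overlap each other."""
    bins = []
    for g in sorted(ann.genes, key=lambda x: x.gene_id):
        seen: dict[tuple[int, int], set[str]] = {}
        for t in g.transcripts:
            for e in t.exons:
                seen.setdefault((e.start, e.end), set()).add(t.transcript_id)
        for s, e in sorted(seen):
            bins.append(
                CountingBin(
                    bin_id=f"{g.gene_id}:E{s}-{e}",
                    feature_id=g.gene_id,
                    intervals=[GenomicInterval(g.chrom, s, e, g.strand)],
                    bin_type="exon",
                    member_transcripts=seen[(s, e)],
                )
            )
    return BinSet(bins, overlap_mode="n/a")


def junction_set(ann: Annotation) -> BinSet:
    """One bin per distinct splice junction per gene.

    Each bin stores the two 1-bp anchors flanking the junction; only
    fragments whose alignment blocks end/start exactly at the junction
    support it.
    """
    bins = []
    for g in sorted(ann.genes, key=lambda x: x.gene_id):
        seen: dict[tuple[int, int], set[str]] = {}
        for t in g.transcripts:
            for d, a in t.junctions():
                seen.setdefault((d, a), set()).add(t.transcript_id)
        for d, a in sorted(seen):
            bins.append(
                CountingBin(
                    bin_id=f"{g.gene_id}:J{d}-{a}",
                    feature_id=g.gene_id,
                    intervals=[
                        GenomicInterval(g.chrom, d - 1, d, g.strand),
                        GenomicInterval(g.chrom, a, a + 1, g.strand),
                    ],
                    bin_type="junction",
                    member_transcripts=seen[(d, a)],
                )
            )
    return BinSet(bins, overlap_mode="n/a")


def transcript_bins(ann: Annotation) -> BinSet:
    """The isoforms themselves as bins (quantified via EM downstream)."""
    bins = []
    for g in sorted(ann.genes, key=lambda x: x.gene_id):
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            bins.append(
                CountingBin(
                    bin_id=t.transcript_id,
                    feature_id=g.gene_id,
                    intervals=list(t.exons),
                    bin_type="transcript",
                    member_transcripts={t.transcript_id},
                )
            )
    return BinSet(bins, overlap_mode="n/a")


# ---------------------------------------------------------------------------
# Catalog editing
# ---------------------------------------------------------------------------

def prefilter_isoforms(
    ann: Annotation,
    abundances: pd.DataFrame,
    threshold: float,
    mode: str = "true_condition",
) -> Annotation:
    """Drop lowly-abundant isoforms from the catalog.

    ``abundances`` holds one row per isoform (column ``isoform_id``) and
    one numeric column per condition (mode ``true_condition``) or per
    sample (mode ``estimated_sample``).  An isoform is dropped iff its
    relative abundance is below ``threshold`` in *both* conditions
    (true_condition), or does not exceed ``threshold`` in *any* sample
    (estimated_sample).  Genes left without isoforms are removed.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    if mode not in ("true_condition", "estimated_sample"):
        raise ValueError(f"invalid mode {mode!r}")
    tab = abundances.set_index("isoform_id")
    value_cols = [
        c for c in tab.columns if c != "gene_id" and pd.api.types.is_numeric_dtype(tab[c])
    ]
    if not value_cols:
        raise ValueError("abundance table has no numeric value columns")
    genes = []
    for g in ann.genes:
        kept = []
        for t in g.transcripts:
            if t.transcript_id not in tab.index:
                raise KeyError(
                    f"isoform {t.transcript_id} missing from abundance table"
                )
            vals = tab.loc[t.transcript_id, value_cols].to_numpy(dtype=float)
            if mode == "true_condition":
                drop = bool(np.all(vals < threshold))
            else:
                drop = bool(np.all(vals <= threshold))
            if not drop:
                kept.append(t)
        if kept:
            genes.append(Gene(g.gene_id, kept))
    return Annotation(
        genes, provenance=f"{ann.provenance}|prefilter({mode},{threshold})"
    )


def degrade_annotation(
    ann: Annotation, fraction: float, truth: pd.DataFrame, seed: int
) -> Annotation:
    """Remove a fraction of transcripts to emulate an incomplete catalog.

    Removal is stratified: the transcripts belonging to a simulated
    differential-usage swap pair form one stratum, all other transcripts
    the second, and round(fraction * n) transcripts are sampled without
    replacement within each stratum, so the loss is proportionally
    distributed between differentially used and other isoforms.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    swapped: set[str] = set()
    for _, row in truth.iterrows():
        if row.get("dtu_status"):
            for col in ("tx_swap_1", "tx_swap_2"):
                v = row.get(col)
                if isinstance(v, str) and v:
                    swapped.add(v)
    all_tids = sorted(ann.transcripts())
    strata = [
        [t for t in all_tids if t in swapped],
        [t for t in all_tids if t not in swapped],
    ]
    rng = np.random.default_rng(seed)
    removed: set[str] = set()
    for stratum in strata:
        k = int(np.floor(fraction * len(stratum) + 0.5))  # round half-up
        if k > 0:
            removed.update(rng.choice(stratum, size=k, replace=False))
    genes = []
    for g in ann.genes:
        kept = [t for t in g.transcripts if t.transcript_id not in removed]
        if kept:
            genes.append(Gene(g.gene_id, kept))
    return Annotation(
        genes, provenance=f"{ann.provenance}|degraded({fraction},seed={seed})"
    )
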