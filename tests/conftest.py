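"""Shared fixtures and independent oracles.

The flattening oracle works per base: every base of a feature is
labelled with the set of transcripts covering it, forbidden bases are
removed, and maximal runs of identical labels become bins.  It shares
no code with the interval arithmetic in the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from dtubench.annotation import Annotation, Gene, GenomicInterval, Transcript


def make_transcript(tid, gid, exon_pairs, chrom="chr1", strand="+"):
    return Transcript(
        tid, gid, [GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs]
    )


def make_gene(gid, exon_lists, chrom="chr1", strand="+"):
    return Gene(
        gid,
        [
            make_transcript(f"{gid}.t{i + 1}", gid, pairs, chrom, strand)
            for i, pairs in enumerate(exon_lists)
        ],
    )


# ---------------------------------------------------------------------------
# Per-base projection oracle for flattening
# ---------------------------------------------------------------------------

def projection_oracle(ann: Annotation, overlap_mode: str):
    """Per-base reference implementation of flattening.

    Returns a set of (feature_id, start, end, frozenset(member tx)).
    """
    gene_bases = {}
    for g in ann.genes:
        bases = set()
        for t in g.transcripts:
            for e in t.exons:
                bases.update(range(e.start, e.end))
        gene_bases[g.gene_id] = bases

    # feature grouping
    if overlap_mode == "aggregate":
        gids = [g.gene_id for g in ann.genes]
        adj = {gid: set() for gid in gids}
        for a in ann.genes:
            for b in ann.genes:
                if a.gene_id >= b.gene_id:
                    continue
                if (
                    a.chrom == b.chrom
                    and a.strand == b.strand
                    and gene_bases[a.gene_id] & gene_bases[b.gene_id]
                ):
                    adj[a.gene_id].add(b.gene_id)
                    adj[b.gene_id].add(a.gene_id)
        seen, groups = set(), []
        for gid in gids:
            if gid in seen:
                continue
            stack, comp = [gid], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            groups.append(sorted(comp))
        features = [("+".join(grp), grp) for grp in groups]
        forbidden_of = {fid: set() for fid, _ in features}
    else:
        features = [(g.gene_id, [g.gene_id]) for g in ann.genes]
        forbidden_of = {}
        for g in ann.genes:
            bad = set()
            for other in ann.genes:
                if other.gene_id == g.gene_id or other.chrom != g.chrom:
                    continue
                if overlap_mode == "exclude_same_strand" and other.strand != g.strand:
                    continue
                bad |= gene_bases[g.gene_id] & gene_bases[other.gene_id]
            forbidden_of[g.gene_id] = bad

    genes_by_id = {g.gene_id: g for g in ann.genes}
    out = set()
    for fid, members in features:
        txs = [t for gid in members for t in genes_by_id[gid].transcripts]
        cover = {}
        for t in txs:
            for e in t.exons:
                for b in range(e.start, e.end):
                    cover.setdefault(b, set()).add(t.transcript_id)
        bad = set().union(*(forbidden_of.get(gid, set()) for gid in members))
        bases = sorted(set(cover) - bad)
        run = None
        for b in bases:
            lab = frozenset(cover[b])
            if run is not None and b == run[1] and lab == run[2]:
                run[1] = b + 1
            else:
                if run is not None:
                    out.add((fid, run[0], run[1], run[2]))
                run = [b, b + 1, lab]
        if run is not None:
            out.add((fid, run[0], run[1], run[2]))
    return out


def binset_as_tuples(binset):
    return {
        (b.feature_id, b.intervals[0].start, b.intervals[0].end,
         frozenset(b.member_transcripts))
        for b in binset.bins
    }


# ---------------------------------------------------------------------------
# Random toy annotations
# ---------------------------------------------------------------------------

def random_annotation(rng, max_genes=5, max_isoforms=6, span=1500):
    """Small random catalog with frequent inter-gene overlap."""
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    for gi in range(n_genes):
        gid = f"g{gi}"
        strand = "+" if rng.random() < 0.7 else "-"
        gstart = int(rng.integers(0, span))
        n_iso = int(rng.integers(1, max_isoforms + 1))
        txs = []
        for ti in range(n_iso):
            n_ex = int(rng.integers(1, 5))
            pos = gstart + int(rng.integers(0, 50))
            exons = []
            for _ in range(n_ex):
                length = int(rng.integers(10, 120))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(5, 80))
            txs.append(make_transcript(f"{gid}.t{ti}", gid, exons, strand=strand))
        genes.append(Gene(gid, txs))
    return Annotation(genes)


@pytest.fixture(scope="session")
def toy_two_isoform():
    """One gene: T1 = [0,100)+[200,300), T2 = [0,100)+[250,300)."""
    return Annotation(
        [make_gene("gA", [[(0, 100), (200, 300)], [(0, 100), (250, 300)]])]
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A shared small simulated experiment (fruit-fly-like regime)."""
    from dtubench import SimParams, simulate_experiment

    params = SimParams(n_genes=40, n_dtu=8, library_size=30_000, seed=11)
    return simulate_experiment(params)
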