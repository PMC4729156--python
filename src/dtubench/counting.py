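"""Fragment counting under each counting-bin paradigm.

The counting unit is the paired-end *fragment*: a fragment contributes
at most one count to any given bin, but a fragment overlapping several
bins is assigned to all of them (so flat/exon bin-count sums can exceed
the number of fragments).  Junction bins count only fragments with a
mate whose alignment blocks split exactly at the junction.  Transcript
bins are quantified by collapsing fragments into equivalence classes of
compatible transcripts and running a uniform-read-model EM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from ncls import NCLS

from .annotation import Annotation, BinSet, Transcript
from .simulate import Fragment

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """bins x samples count table with a bin -> feature grouping."""

    bin_ids: list[str]
    feature_ids: list[str]
    samples: list[str]
    counts: np.ndarray
    bin_type: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.bin_ids), len(self.samples)):
            raise ValueError("count matrix dimensions inconsistent")
        if len(self.feature_ids) != len(self.bin_ids):
            raise ValueError("feature_ids must parallel bin_ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def to_tsv(self, path, feature_map_path=None) -> None:
        df = pd.DataFrame(
            np.round(self.counts, 6), index=self.bin_ids, columns=self.samples
        )
        df.index.name = "bin_id"
        df.to_csv(path, sep="\t")
        if feature_map_path is not None:
            pd.DataFrame(
                {"bin_id": self.bin_ids, "feature_id": self.feature_ids}
            ).to_csv(feature_map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, feature_map_path, bin_type="flat") -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="bin_id")
        fmap = pd.read_csv(feature_map_path, sep="\t", index_col="bin_id")
        features = fmap.loc[df.index, "feature_id"].tolist()
        return cls(
            bin_ids=[str(b) for b in df.index],
            feature_ids=[str(f) for f in features],
            samples=[str(s) for s in df.columns],
            counts=df.to_numpy(dtype=float),
            bin_type=bin_type,
        )


@dataclass
class EquivalenceClass:
    """A set of transcripts and the per-sample number of fragments whose
    alignments are compatible with exactly that set."""

    transcript_set: frozenset
    count: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Fragment tables
# ---------------------------------------------------------------------------

def fragment_block_table(fragments: list[Fragment]) -> pd.DataFrame:
    """Flatten fragments into one row per alignment block.

    Columns: uid (fragment index), sample, mate, start, end.  Counting
    functions accept this table directly, so it can be built once and
    reused across counting paradigms.
    """
    uid, sample, mate, start, end = [], [], [], [], []
    for i, f in enumerate(fragments):
        for m, blocks in ((1, f.mate1_blocks), (2, f.mate2_blocks)):
            for b in blocks:
                uid.append(i)
                sample.append(f.sample_id)
                mate.append(m)
                start.append(b.start)
                end.append(b.end)
    return pd.DataFrame(
        {
            "uid": np.asarray(uid, dtype=np.int64),
            "sample": pd.Categorical(sample),
            "mate": np.asarray(mate, dtype=np.int8),
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
        }
    )


def _as_block_table(fragments) -> pd.DataFrame:
    if isinstance(fragments, pd.DataFrame):
        return fragments
    return fragment_block_table(fragments)


def _sample_order(blocks: pd.DataFrame) -> list[str]:
    return sorted(map(str, blocks["sample"].unique()))


# ---------------------------------------------------------------------------
# Overlap counting (flat and exon bins)
# ---------------------------------------------------------------------------

def count_flat_or_exon(fragments, binset: BinSet) -> CountMatrix:
    """Count fragments into flat or exon bins by >= 1 bp overlap.

    A fragment contributes +1 to every bin overlapped by the union of
    its mates' blocks, at most once per (fragment, bin).
    """
    if binset.bin_type not in ("flat", "exon"):
        raise ValueError("binset must hold flat or exon bins")
    blocks = _as_block_table(fragments)
    samples = _sample_order(blocks)
    n_bins = len(binset.bins)
    iv_start, iv_end, iv_bin = [], [], []
    for bi, b in enumerate(binset.bins):
        for iv in b.intervals:
            iv_start.append(iv.start)
            iv_end.append(iv.end)
            iv_bin.append(bi)
    counts = np.zeros((n_bins, len(samples)))
    if not blocks.empty and iv_start:
        tree = NCLS(
            np.asarray(iv_start, dtype=np.int64),
            np.asarray(iv_end, dtype=np.int64),
            np.arange(len(iv_start), dtype=np.int64),
        )
        qidx, ividx = tree.all_overlaps_both(
            blocks["start"].to_numpy(np.int64),
            blocks["end"].to_numpy(np.int64),
            np.arange(len(blocks), dtype=np.int64),
        )
        if len(qidx):
            uid = blocks["uid"].to_numpy()[qidx]
            scode = blocks["sample"].cat.codes.to_numpy()[qidx]
            bin_of = np.asarray(iv_bin, dtype=np.int64)[ividx]
            # dedupe (fragment, bin) pairs
            key = np.unique(
                np.stack([uid, bin_of, scode], axis=1), axis=0
            )
            cat_levels = list(blocks["sample"].cat.categories)
            col = np.array([samples.index(str(c)) for c in cat_levels])
            np.add.at(counts, (key[:, 1], col[key[:, 2]]), 1.0)
    return CountMatrix(
        bin_ids=[b.bin_id for b in binset.bins],
        feature_ids=[b.feature_id for b in binset.bins],
        samples=samples,
        counts=counts,
        bin_type=binset.bin_type,
    )


# ---------------------------------------------------------------------------
# Junction counting
# ---------------------------------------------------------------------------

def count_junctions(fragments, binset: BinSet) -> CountMatrix:
    """Count junction-spanning fragments.

    A fragment supports junction (d, a) iff either mate has two
    consecutive blocks ending exactly at d and starting exactly at a;
    fragments contained in exons contribute nothing.
    """
    if binset.bin_type != "junction":
        raise ValueError("binset must hold junction bins")
    blocks = _as_block_table(fragments)
    samples = _sample_order(blocks)
    n_bins = len(binset.bins)
    counts = np.zeros((n_bins, len(samples)))
    junc_rows = []
    for bi, b in enumerate(binset.bins):
        d = b.intervals[0].end
        a = b.intervals[1].start
        junc_rows.append((d, a, bi))
    jtab = pd.DataFrame(junc_rows, columns=["donor", "acceptor", "bin"])
    if blocks.empty or jtab.empty:
        pass
    else:
        b = blocks.sort_values(["uid", "mate", "start"], kind="stable")
        same_mate = (
            (b["uid"].to_numpy()[:-1] == b["uid"].to_numpy()[1:])
            & (b["mate"].to_numpy()[:-1] == b["mate"].to_numpy()[1:])
        )
        donors = b["end"].to_numpy()[:-1][same_mate]
        acceptors = b["start"].to_numpy()[1:][same_mate]
        uids = b["uid"].to_numpy()[:-1][same_mate]
        scode = b["sample"].cat.codes.to_numpy()[:-1][same_mate]
        obs = pd.DataFrame(
            {"donor": donors, "acceptor": acceptors, "uid": uids, "scode": scode}
        )
        hit = obs.merge(jtab, on=["donor", "acceptor"])
        if not hit.empty:
            key = hit[["uid", "bin", "scode"]].drop_duplicates()
            cat_levels = list(blocks["sample"].cat.categories)
            col = np.array([samples.index(str(c)) for c in cat_levels])
            np.add.at(
                counts,
                (key["bin"].to_numpy(), col[key["scode"].to_numpy()]),
                1.0,
            )
    return CountMatrix(
        bin_ids=[b.bin_id for b in binset.bins],
        feature_ids=[b.feature_id for b in binset.bins],
        samples=samples,
        counts=counts,
        bin_type="junction",
    )


# ---------------------------------------------------------------------------
# Equivalence classes and EM quantification
# ---------------------------------------------------------------------------

def _mate_compatible(blocks, tx: Transcript) -> bool:
    """A mate is compatible with tx iff its blocks lie within tx's exons
    and every internal block boundary coincides with a tx junction."""
    exons = tx.exons
    # locate the exon containing the first block
    ei = None
    for k, e in enumerate(exons):
        if e.start <= blocks[0].start and blocks[0].end <= e.end:
            ei = k
            break
        if e.start <= blocks[0].start < e.end:
            return False  # starts inside but pokes out
    if ei is None:
        return False
    if len(blocks) == 1:
        return True
    if blocks[0].end != exons[ei].end:
        return False
    for b in blocks[1:-1]:
        ei += 1
        if ei >= len(exons):
            return False
        if b.start != exons[ei].start or b.end != exons[ei].end:
            return False
    ei += 1
    last = blocks[-1]
    if ei >= len(exons):
        return False
    return last.start == exons[ei].start and last.end <= exons[ei].end


def fragment_compatibility(fragment: Fragment, tx: Transcript) -> bool:
    return _mate_compatible(fragment.mate1_blocks, tx) and _mate_compatible(
        fragment.mate2_blocks, tx
    )


def build_equivalence_classes(
    fragments: list[Fragment], ann: Annotation
) -> tuple[list[EquivalenceClass], dict[str, int]]:
    """Collapse fragments into equivalence classes of compatible
    transcripts.

    Returns the classes and a per-sample tally of fragments compatible
    with no transcript (discarded; most background fragments land here).
    """
    txs = list(ann.transcripts().values())
    spans = [(t.span.start, t.span.end) for t in txs]
    tree = NCLS(
        np.array([s for s, _ in spans], dtype=np.int64),
        np.array([e for _, e in spans], dtype=np.int64),
        np.arange(len(txs), dtype=np.int64),
    )
    ecs: dict[frozenset, dict[str, int]] = {}
    discarded: dict[str, int] = {}
    for f in fragments:
        lo = min(f.mate1_blocks[0].start, f.mate2_blocks[0].start)
        hi = max(f.mate1_blocks[-1].end, f.mate2_blocks[-1].end)
        _, cand = tree.all_overlaps_both(
            np.array([lo], dtype=np.int64),
            np.array([hi], dtype=np.int64),
            np.array([0], dtype=np.int64),
        )
        compat = frozenset(
            txs[i].transcript_id
            for i in cand
            if spans[i][0] <= lo and hi <= spans[i][1]
            and fragment_compatibility(f, txs[i])
        )
        if not compat:
            discarded[f.sample_id] = discarded.get(f.sample_id, 0) + 1
            continue
        ecs.setdefault(compat, {})
        ecs[compat][f.sample_id] = ecs[compat].get(f.sample_id, 0) + 1
    out = [
        EquivalenceClass(ts, dict(cnt))
        for ts, cnt in sorted(ecs.items(), key=lambda kv: sorted(kv[0]))
    ]
    return out, discarded


def em_loglik(theta: np.ndarray, ec_idx: list[np.ndarray], ec_n: np.ndarray,
              eff_len: np.ndarray) -> float:
    """Log-likelihood of EC counts under the uniform-read model:
    P(fragment in ec) = sum_{t in ec} theta_t / L_t."""
    ll = 0.0
    for idx, n in zip(ec_idx, ec_n):
        p = float(np.sum(theta[idx] / eff_len[idx]))
        if p <= 0:
            return -np.inf
        ll += n * np.log(p)
    return ll


def em_quantify(
    ecs: list[EquivalenceClass],
    effective_lengths: dict[str, float],
    max_iter: int = 1000,
    tol: float = 1e-8,
    transcripts: list[str] | None = None,
) -> CountMatrix:
    """Abundance EM over equivalence classes, per sample.

    theta (the read-fraction parameter) starts uniform; the E-step
    splits each class's count among its transcripts proportionally to
    theta_t / effective length, and the M-step renormalizes.  Output is
    expected read counts per transcript (real-valued).
    """
    if transcripts is None:
        transcripts = sorted({t for ec in ecs for t in ec.transcript_set})
    t_index = {t: i for i, t in enumerate(transcripts)}
    samples = sorted({s for ec in ecs for s in ec.count})
    counts = np.zeros((len(transcripts), len(samples)))
    if not ecs or not transcripts:
        return CountMatrix(
            bin_ids=list(transcripts),
            feature_ids=list(transcripts),
            samples=samples,
            counts=counts,
            bin_type="transcript",
        )
    for t in transcripts:
        if effective_lengths.get(t, 0) < 1:
            raise ValueError(f"transcript {t} lacks effective length >= 1")
    eff = np.array([effective_lengths[t] for t in transcripts])
    ec_idx = [
        np.array(sorted(t_index[t] for t in ec.transcript_set), dtype=int)
        for ec in ecs
    ]
    for si, s in enumerate(samples):
        n = np.array([ec.count.get(s, 0) for ec in ecs], dtype=float)
        N = n.sum()
        if N == 0:
            continue
        theta = np.full(len(transcripts), 1.0 / len(transcripts))
        for _ in range(max_iter):
            assigned = np.zeros(len(transcripts))
            for idx, cnt in zip(ec_idx, n):
                if cnt == 0:
                    continue
                w = theta[idx] / eff[idx]
                tot = w.sum()
                if tot > 0:
                    assigned[idx] += cnt * w / tot
            new_theta = assigned / N
            delta = float(np.max(np.abs(new_theta - theta)))
            theta = new_theta
            if delta < tol:
                break
        counts[:, si] = N * theta
    return CountMatrix(
        bin_ids=list(transcripts),
        feature_ids=list(transcripts),
        samples=samples,
        counts=counts,
        bin_type="transcript",
    )


def transcript_count_matrix(
    fragments: list[Fragment], ann: Annotation,
    effective_lengths: dict[str, float],
    samples: list[str] | None = None,
) -> CountMatrix:
    """Equivalence classes + EM, with feature ids set to gene ids.

    Transcripts receiving no compatible fragment still appear with zero
    counts, so every annotated isoform has a bin.
    """
    ecs, discarded = build_equivalence_classes(fragments, ann)
    if discarded:
        logger.info("fragments compatible with no transcript: %s", discarded)
    all_tids = sorted(ann.transcripts())
    cm = em_quantify(ecs, effective_lengths, transcripts=all_tids)
    if samples is not None:
        missing = [s for s in samples if s not in cm.samples]
        if missing:
            full = np.zeros((len(cm.bin_ids), len(samples)))
            for j, s in enumerate(samples):
                if s in cm.samples:
                    full[:, j] = cm.counts[:, cm.samples.index(s)]
            cm = CountMatrix(cm.bin_ids, cm.feature_ids, list(samples), full,
                             "transcript")
    gene_of = {
        t.transcript_id: t.gene_id for t in ann.transcripts().values()
    }
    cm.feature_ids = [gene_of[t] for t in cm.bin_ids]
    return cm
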