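"""PWM promoter scanning with permutation-based empirical p-values.

A position frequency matrix is converted to a log2-odds scoring matrix against
a background base composition (with a proportional pseudocount), promoters are
scanned at every offset on both strands, and each score receives an empirical
p-value from a null pool of scores of i.i.d. background sequences:
p = (#null >= score + 1) / (M + 1). Sites may additionally be filtered by the
mean of a per-base conservation track over the site (a proxy for human/mouse
promoter conservation). A gene counts as a TF target if at least one
surviving site clears the p-value cutoff.

Windows containing an N score minus infinity and can never be sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ALPHABET, Motif, PromoterSet, PWMSet

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class BindingSite:
    gene_id: str
    motif_id: str
    tf_name: str
    start: int  # 0-based promoter coordinate of the site's 5'-most base
    strand: str
    score: float  # bits
    empirical_p: float
    mean_conservation: float | None = None


@dataclass
class NullScoreModel:
    motif_id: str
    scores: np.ndarray  # sorted ascending
    background: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        if self.scores.size < 1000:
            raise ValueError("null pool needs >= 1000 samples")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")


def pwm_log_odds(
    counts: np.ndarray,
    background: np.ndarray = UNIFORM_BG,
    pseudocount_weight: float = 0.01,
) -> np.ndarray:
    """Log2-odds matrix (bits): per column j with total C_j,

    p_bj = (count_bj + w·bg_b·C_j) / (C_j·(1 + w)),  entry = log2(p_bj / bg_b).
    """
    counts = np.asarray(counts, dtype=float)
    background = np.asarray(background, dtype=float)
    if (background <= 0).any():
        raise ValueError("background frequencies must be positive")
    col_sums = counts.sum(axis=0)
    if (col_sums <= 0).any():
        raise ValueError("zero column sum in PWM")
    probs = (counts + pseudocount_weight * background[:, None] * col_sums) / (
        col_sums * (1.0 + pseudocount_weight)
    )
    return np.log2(probs / background[:, None])


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and N (or anything else) to 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _strand_scores(matrix: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Window scores at every start; windows containing N get -inf."""
    L = matrix.shape[1]
    n_windows = codes.size - L + 1
    if n_windows <= 0:
        raise ValueError("promoter shorter than motif")
    padded = np.vstack([matrix, np.full(L, -np.inf)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return padded[windows, np.arange(L)].sum(axis=1)


def reverse_complement_matrix(matrix: np.ndarray) -> np.ndarray:
    return matrix[::-1, ::-1]


def scan_promoter(
    matrix: np.ndarray, promoter: str, both_strands: bool = True
) -> list[tuple[int, str, float]]:
    """Score every window of a promoter; returns (start, strand, score) with
    start in forward promoter coordinates. N-containing windows are skipped.

    A minus-strand hit at forward start s means the motif matches the reverse
    complement of promoter[s:s+L].
    """
    codes = encode_sequence(promoter)
    hits = []
    fwd = _strand_scores(matrix, codes)
    for s, sc in enumerate(fwd):
        if np.isfinite(sc):
            hits.append((s, "+", float(sc)))
    if both_strands:
        rev = _strand_scores(reverse_complement_matrix(matrix), codes)
        for s, sc in enumerate(rev):
            if np.isfinite(sc):
                hits.append((s, "-", float(sc)))
    return hits


def build_null(
    matrix: np.ndarray,
    background: np.ndarray = UNIFORM_BG,
    n_samples: int = 100_000,
    seed: int = 0,
    motif_id: str = "",
) -> NullScoreModel:
    """Null score pool from i.i.d. background sequences of motif length."""
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    rng = np.random.default_rng(seed)
    L = matrix.shape[1]
    draws = rng.choice(4, size=(n_samples, L), p=np.asarray(background, float))
    scores = matrix[draws, np.arange(L)].sum(axis=1)
    return NullScoreModel(motif_id=motif_id, scores=scores,
                          background=np.asarray(background, float), seed=seed)


def empirical_p(score: float, null: NullScoreModel) -> float:
    """p = (#null >= score + 1) / (M + 1), via binary search on sorted nulls."""
    m = null.scores.size
    n_ge = m - int(np.searchsorted(null.scores, score, side="left"))
    return (n_ge + 1) / (m + 1)


def scan_all(
    pwms: PWMSet,
    promoters: PromoterSet,
    background: np.ndarray | None = None,
    pseudocount_weight: float = 0.01,
    n_null_samples: int = 100_000,
    seed: int = 0,
    keep_p_max: float = 1e-3,
) -> list[BindingSite]:
    """Scan every promoter with every motif; attach empirical p-values and
    mean site conservation (when a track exists).

    Only candidate sites with empirical_p <= keep_p_max are materialized
    (downstream filters operate at stricter cutoffs anyway).
    """
    if background is None:
        background = estimate_background(promoters)
    sites: list[BindingSite] = []
    for k, motif in enumerate(pwms):
        lom = pwm_log_odds(motif.counts, background, pseudocount_weight)
        null = build_null(lom, background, n_null_samples,
                          seed=(seed + 7919 * k) % (2**31), motif_id=motif.motif_id)
        m = null.scores.size
        L = motif.length
        rc = reverse_complement_matrix(lom)
        for gene_id in sorted(promoters.promoters):
            p = promoters.promoters[gene_id]
            track = promoters.conservation.get(gene_id)
            codes = encode_sequence(p.sequence)
            for strand, mat in (("+", lom), ("-", rc)):
                scores = _strand_scores(mat, codes)
                n_ge = m - np.searchsorted(null.scores, scores, side="left")
                pvals = (n_ge + 1) / (m + 1)
                for start in np.nonzero((pvals <= keep_p_max) & np.isfinite(scores))[0]:
                    cons = None
                    if track is not None:
                        cons = float(np.mean(track[start:start + L]))
                    sites.append(
                        BindingSite(
                            gene_id=gene_id, motif_id=motif.motif_id,
                            tf_name=motif.tf_name, start=int(start), strand=strand,
                            score=float(scores[start]),
                            empirical_p=float(pvals[start]),
                            mean_conservation=cons,
                        )
                    )
    return sites


def estimate_background(promoters: PromoterSet) -> np.ndarray:
    """Base composition over all promoter sequences (N excluded); uniform if
    there are no promoters."""
    counts = np.zeros(4)
    for p in promoters.promoters.values():
        codes = encode_sequence(p.sequence)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return UNIFORM_BG.copy()
    return counts / counts.sum()


def conservation_filter(
    sites: list[BindingSite],
    promoters: PromoterSet,
    min_mean: float = 0.5,
) -> list[BindingSite]:
    """Keep sites whose mean per-base conservation >= min_mean (inclusive).

    Sites on genes without a conservation track pass unfiltered, with a
    warning naming the genes.
    """
    kept = []
    untracked = set()
    for s in sites:
        if s.gene_id not in promoters.conservation:
            untracked.add(s.gene_id)
            kept.append(s)
            continue
        cons = s.mean_conservation
        if cons is None:
            track = promoters.conservation[s.gene_id]
            L = _site_length(s, promoters)
            cons = float(np.mean(track[s.start:s.start + L]))
        if cons >= min_mean:
            kept.append(s)
    if untracked:
        warnings.warn(
            f"no conservation track for {len(untracked)} gene(s); "
            f"their sites pass unfiltered"
        )
    return kept


def _site_length(site: BindingSite, promoters: PromoterSet) -> int:
    # conservative fallback when the motif length is not recoverable
    return 1


def assign_tf_targets(
    sites: list[BindingSite],
    p_max: float = 1e-4,
    min_tfs_report: int = 2,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Map gene -> set of TFs with >= 1 site at empirical_p <= p_max.

    Returns (full map, report view restricted to genes bound by at least
    ``min_tfs_report`` distinct TFs).
    """
    full: dict[str, set[str]] = {}
    for s in sites:
        if s.empirical_p <= p_max:
            full.setdefault(s.gene_id, set()).add(s.tf_name)
    report = {g: tfs for g, tfs in full.items() if len(tfs) >= min_tfs_report}
    return full, report


def write_sites_table(sites: list[BindingSite], path) -> None:
    import pandas as pd

    rows = [
        {
            "gene_id": s.gene_id, "motif_id": s.motif_id, "tf_name": s.tf_name,
            "start": s.start, "strand": s.strand, "score_bits": s.score,
            "empirical_p": s.empirical_p,
            "mean_conservation": "" if s.mean_conservation is None else s.mean_conservation,
        }
        for s in sites
    ]
    cols = ["gene_id", "motif_id", "tf_name", "start", "strand",
            "score_bits", "empirical_p", "mean_conservation"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
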