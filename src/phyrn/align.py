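"""Query-versus-PSSM local alignment and the PHYRN product score.

Every query sequence is aligned to every profile in the library with a
Smith-Waterman / Gotoh local aligner operating on the profile's
position-specific score rows.  The best positive alignment is summarized
as counts (identities, alignment length, query-residue length, profile
length) and condensed into the product score

    product = %identity x %coverage
            = (ids / alen) x (aqlen / plen)

which equals (1 - p_ARP)(1 - w_g): the complement of the
alignment-restricted p-distance times the complement of the gap weight.
The score is a fraction in [0, 1]; 0 encodes "no positive alignment".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .dayhoff import AA_INDEX
from .profiles import PSSM, PSSMLibrary

__all__ = [
    "AlignmentStats",
    "ProductScoreMatrix",
    "align_to_pssm",
    "percent_identity",
    "percent_coverage",
    "product_score",
    "arp_gapweight_decomposition",
    "populate_matrix",
]

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

_OP_MATCH, _OP_QGAP, _OP_INS = 0, 1, 2


@dataclass(frozen=True)
class AlignmentStats:
    """Counts of one query-vs-PSSM local alignment.

    ids: identical residues (query residue equals the profile's seed
    residue at the aligned position); alen: alignment columns including
    gaps; aqlen: columns carrying a query residue; plen: profile length;
    gap_chars: columns where the query has a gap (= alen - aqlen).
    """

    ids: int
    alen: int
    aqlen: int
    plen: int
    gap_chars: int
    raw_score: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.ids <= self.alen):
            raise ValueError("need 0 <= ids <= alen")
        if not (0 < self.aqlen <= self.alen):
            raise ValueError("need 0 < aqlen <= alen")
        if self.gap_chars != self.alen - self.aqlen:
            raise ValueError("gap_chars must equal alen - aqlen")
        if self.plen < 1:
            raise ValueError("plen must be >= 1")


def encode_sequence(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue outside the 20-letter alphabet: {exc}") from exc


@njit(cache=True)
def _sw_kernel(scores, qidx, gap_open, gap_extend):  # pragma: no cover - jit
    """Gotoh local alignment of a residue index vector against score rows.

    A maximal gap run of length L costs gap_open + L * gap_extend.  Returns
    (best score, ops, n_ops, end_i, end_j); ops[0] is the LAST alignment
    column and ops[n_ops-1] the first, with 0 = residue-vs-position,
    1 = gap in query (profile position skipped), 2 = query insertion.
    Ties prefer the earlier (row-major) end cell and, within a cell, the
    diagonal over gap states, so the traceback is deterministic.
    """
    lq = qidx.shape[0]
    lp = scores.shape[0]
    open_cost = gap_open + gap_extend

    h_prev = np.zeros(lp + 1)
    h_cur = np.zeros(lp + 1)
    f_col = np.full(lp + 1, -1e30)
    ptr_h = np.zeros((lq + 1, lp + 1), dtype=np.int8)
    ptr_e = np.zeros((lq + 1, lp + 1), dtype=np.int8)
    ptr_f = np.zeros((lq + 1, lp + 1), dtype=np.int8)

    best = 0.0
    best_i = 0
    best_j = 0
    for i in range(1, lq + 1):
        e_row = -1e30
        h_cur[0] = 0.0
        for j in range(1, lp + 1):
            e_open = h_cur[j - 1] - open_cost
            e_ext = e_row - gap_extend
            if e_open >= e_ext:
                e_row = e_open
                ptr_e[i, j] = 0
            else:
                e_row = e_ext
                ptr_e[i, j] = 1
            f_open = h_prev[j] - open_cost
            f_ext = f_col[j] - gap_extend
            if f_open >= f_ext:
                f_col[j] = f_open
                ptr_f[i, j] = 0
            else:
                f_col[j] = f_ext
                ptr_f[i, j] = 1
            diag = h_prev[j - 1] + scores[j - 1, qidx[i - 1]]
            val = 0.0
            p = 0
            if diag >= val and diag > 0.0:
                val = diag
                p = 1
            if e_row > val:
                val = e_row
                p = 2
            if f_col[j] > val:
                val = f_col[j]
                p = 3
            h_cur[j] = val
            ptr_h[i, j] = p
            if val > best:
                best = val
                best_i = i
                best_j = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp

    ops = np.empty(lq + lp, dtype=np.int8)
    n_ops = 0
    i, j = best_i, best_j
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 or j > 0:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                ops[n_ops] = _OP_MATCH
                n_ops += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[n_ops] = _OP_QGAP
            n_ops += 1
            if ptr_e[i, j] == 0:
                state = 0
            j -= 1
        else:
            ops[n_ops] = _OP_INS
            n_ops += 1
            if ptr_f[i, j] == 0:
                state = 0
            i -= 1
    return best, ops[:n_ops], n_ops, best_i, best_j


def _raw_alignment(query_idx: np.ndarray, pssm: PSSM, gap_open: float,
                   gap_extend: float):
    score, ops, n_ops, end_i, end_j = _sw_kernel(
        np.ascontiguousarray(pssm.scores), query_idx,
        float(gap_open), float(gap_extend),
    )
    if score <= 0.0 or n_ops == 0:
        return None
    return score, ops, end_i, end_j


def align_to_pssm(
    query: str,
    pssm: PSSM,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentStats | None:
    """Best positive local alignment of ``query`` against ``pssm``.

    Returns None ("no hit") iff no alignment scores above zero.
    """
    if not query:
        raise ValueError("query must be nonempty")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be > 0")
    qidx = encode_sequence(query)
    raw = _raw_alignment(qidx, pssm, gap_open, gap_extend)
    if raw is None:
        return None
    score, ops, end_i, end_j = raw
    seed_idx = pssm.seed_indices
    ids = 0
    aqlen = 0
    gap_chars = 0
    i, j = end_i, end_j  # 1-based cursors at the alignment end
    for op in ops:  # ops run from the alignment end backwards
        if op == _OP_MATCH:
            if qidx[i - 1] == seed_idx[j - 1]:
                ids += 1
            aqlen += 1
            i -= 1
            j -= 1
        elif op == _OP_QGAP:
            gap_chars += 1
            j -= 1
        else:
            aqlen += 1
            i -= 1
    return AlignmentStats(
        ids=ids,
        alen=int(len(ops)),
        aqlen=aqlen,
        plen=pssm.plen,
        gap_chars=gap_chars,
        raw_score=float(score),
    )


# ----------------------------------------------------------------------
# score algebra
# ----------------------------------------------------------------------
def percent_identity(stats: AlignmentStats) -> float:
    """Identical residues over alignment length including gaps."""
    if stats.alen <= 0:
        raise ValueError("alen must be > 0")
    return stats.ids / stats.alen


def percent_coverage(stats: AlignmentStats) -> float:
    """Query-residue alignment length over profile length, clamped to 1."""
    if stats.plen <= 0:
        raise ValueError("plen must be > 0")
    return min(stats.aqlen / stats.plen, 1.0)


def product_score(stats: AlignmentStats) -> float:
    """%identity x %coverage, a fraction in [0, 1]."""
    return percent_identity(stats) * percent_coverage(stats)


def arp_gapweight_decomposition(stats: AlignmentStats) -> tuple[float, float]:
    """(p_ARP, w_g): alignment-restricted p-distance and gap weight.

    (1 - p_ARP)(1 - w_g) equals the product score whenever the coverage
    clamp is inactive (aqlen <= plen).
    """
    if stats.plen <= 0 or stats.alen <= 0:
        raise ValueError("plen and alen must be > 0")
    p_arp = (stats.plen - stats.ids) / stats.plen
    w_g = stats.gap_chars / stats.alen
    return p_arp, w_g


# ----------------------------------------------------------------------
# the N x M matrix
# ----------------------------------------------------------------------
@dataclass
class ProductScoreMatrix:
    """N queries x M profiles product-score matrix; 0 = no alignment."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    metadata: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match id lists")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("product scores must lie in [0, 1]")

    def write_tsv(self, path) -> None:
        """TSV with row/column headers; metadata goes to a JSON sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        with open(path, "w") as fh:
            fh.write("query\t" + "\t".join(self.col_ids) + "\n")
            for i, rid in enumerate(self.row_ids):
                row = "\t".join(repr(float(x)) for x in self.values[i])
                fh.write(f"{rid}\t{row}\n")
        if self.metadata is not None:
            sidecar = path.with_suffix(path.suffix + ".meta.json")
            sidecar.write_text(json.dumps(self.metadata, sort_keys=True, indent=1)
                               + "\n")

    @classmethod
    def read_tsv(cls, path) -> "ProductScoreMatrix":
        import json
        from pathlib import Path

        path = Path(path)
        with open(path) as fh:
            col_ids = fh.readline().rstrip("\n").split("\t")[1:]
            row_ids = []
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                row_ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(sidecar.read_text()) if sidecar.exists() else None
        return cls(np.array(rows), row_ids, col_ids, metadata)


def populate_matrix(
    queries: dict[str, str],
    library: PSSMLibrary,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    evalue_max: float = 1e10,
) -> ProductScoreMatrix:
    """Product score of every query against every library profile.

    The e-value ceiling of 1e10 is the "keep everything" setting: every
    positive local alignment contributes; a no-hit cell is encoded as 0.
    """
    if not queries or not library.pssms:
        raise ValueError("queries and library must be nonempty")
    ids = list(queries)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate query ids")
    del evalue_max  # any positive alignment is kept
    values = np.zeros((len(ids), len(library.pssms)))
    encoded = {qid: encode_sequence(seq) for qid, seq in queries.items()}
    for m, pssm in enumerate(library.pssms):
        scores = np.ascontiguousarray(pssm.scores)
        seed_idx = pssm.seed_indices
        for n, qid in enumerate(ids):
            qidx = encoded[qid]
            score, ops, n_ops, end_i, end_j = _sw_kernel(
                scores, qidx, float(gap_open), float(gap_extend)
            )
            if score <= 0.0 or n_ops == 0:
                continue
            idents = 0
            aqlen = 0
            i, j = end_i, end_j
            for op in ops:
                if op == _OP_MATCH:
                    if qidx[i - 1] == seed_idx[j - 1]:
                        idents += 1
                    aqlen += 1
                    i -= 1
                    j -= 1
                elif op == _OP_QGAP:
                    j -= 1
                else:
                    aqlen += 1
                    i -= 1
            pid = idents / n_ops
            cov = min(aqlen / pssm.plen, 1.0)
            values[n, m] = pid * cov
    return ProductScoreMatrix(
        values=values,
        row_ids=ids,
        col_ids=[p.source_id for p in library.pssms],
        metadata={
            "gap_open": gap_open,
            "gap_extend": gap_extend,
            "score_scale": "fraction",
            "library_fingerprint": library.fingerprint(),
        },
    )
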