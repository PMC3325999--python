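"""Query-based PSSM library construction by iterative profile gathering.

Each query seeds a profile.  The profile is searched against a sequence
database; matches below the e-value cutoff are added to the member set,
the profile is rebuilt from all members, and the search repeats until no
new member appears or the iteration cap is reached.  The default database
is the query set itself: synthetic families have no outside homologs, so
profile signal comes entirely from within the family.

E-values are Karlin-Altschul-style: an extreme-value (Gumbel) law is
fitted by moments to scores of the profile against shuffled database
sequences, and the fitted tail probability is multiplied by the database
size.  This is a desk-scale stand-in for BLAST statistics: monotone in the
raw score, deterministic under a fixed seed, but not bit-compatible with
NCBI e-values.

Profiles are position frequency/score matrices over the seed coordinates:
member residue frequencies (sequence-weighted, gaps excluded) are blended
with the background via a single pseudocount weight, and the score is the
log2 odds of the blended frequency against the background.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dayhoff import AA_INDEX, ALPHABET, EQUILIBRIUM_FREQS

__all__ = [
    "PSSM",
    "PSSMLibrary",
    "build_pssm",
    "gather_homologs",
    "build_library",
]

_EULER_GAMMA = 0.5772156649015329


@dataclass
class PSSM:
    """Position-specific scoring matrix anchored on a seed sequence."""

    source_id: str
    seed_seq: str
    scores: np.ndarray  # plen x 20 log2-odds
    freqs: np.ndarray   # plen x 20, rows sum to 1
    background: np.ndarray  # 20-vector

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.shape != (len(self.seed_seq), 20):
            raise ValueError("scores must be plen x 20")
        if self.freqs.shape != self.scores.shape:
            raise ValueError("freqs must match scores shape")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def plen(self) -> int:
        return len(self.seed_seq)

    @property
    def seed_indices(self) -> np.ndarray:
        return np.array([AA_INDEX[a] for a in self.seed_seq], dtype=np.int64)


@dataclass
class PSSMLibrary:
    """Ordered set of PSSMs; the order defines matrix column order."""

    pssms: list[PSSM]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.source_id for p in self.pssms]
        if len(set(ids)) != len(ids):
            raise ValueError("PSSM source_ids must be unique")

    def __len__(self) -> int:
        return len(self.pssms)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for pssm in self.pssms:
            h.update(pssm.source_id.encode())
            h.update(pssm.seed_seq.encode())
            h.update(np.ascontiguousarray(pssm.scores).tobytes())
        return h.hexdigest()[:16]

    # ------------------------------------------------------------------
    # plain-text serialization (bit-exact round trip via shortest repr)
    # ------------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#PHYRN-PSSM-LIBRARY\tv1\n")
            fh.write(f"#metadata\t{json.dumps(self.metadata, sort_keys=True)}\n")
            fh.write(f"#n_pssms\t{len(self.pssms)}\n")
            for pssm in self.pssms:
                fh.write(f">{pssm.source_id}\tplen={pssm.plen}\n")
                fh.write(f"#seed\t{pssm.seed_seq}\n")
                fh.write("#background\t"
                         + "\t".join(repr(float(x)) for x in pssm.background) + "\n")
                for p in range(pssm.plen):
                    row = [repr(float(x)) for x in pssm.scores[p]]
                    row += [repr(float(x)) for x in pssm.freqs[p]]
                    fh.write("\t".join(row) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "PSSMLibrary":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#PHYRN-PSSM-LIBRARY"):
                raise ValueError(f"{path}: not a PHYRN PSSM library file")
            metadata = json.loads(fh.readline().split("\t", 1)[1])
            n = int(fh.readline().split("\t", 1)[1])
            pssms = []
            for _ in range(n):
                name_line = fh.readline().strip()
                source_id = name_line[1:].split("\t")[0]
                seed = fh.readline().strip().split("\t", 1)[1]
                background = np.array(
                    [float(x) for x in fh.readline().strip().split("\t")[1:]]
                )
                scores = np.empty((len(seed), 20))
                freqs = np.empty((len(seed), 20))
                for p in range(len(seed)):
                    vals = [float(x) for x in fh.readline().split("\t")]
                    scores[p] = vals[:20]
                    freqs[p] = vals[20:]
                pssms.append(PSSM(source_id, seed, scores, freqs, background))
        return cls(pssms, metadata)


def _validate_protein(seq: str, name: str) -> None:
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"{name}: non-amino-acid symbols {sorted(bad)}")


def _henikoff_weights(rows: list[str]) -> np.ndarray:
    """Position-based sequence weights, normalized to sum to len(rows)."""
    n = len(rows)
    plen = len(rows[0])
    weights = np.zeros(n)
    for p in range(plen):
        col = [row[p] for row in rows]
        residues = [c for c in col if c != "-"]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for i, c in enumerate(col):
            if c != "-":
                weights[i] += 1.0 / (r * counts[c])
    if weights.sum() == 0:
        weights[:] = 1.0
    return weights * (n / weights.sum())


def build_pssm(
    seed_seq: str,
    matches: list[str] | None = None,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    weighting: str = "henikoff",
    source_id: str = "query",
) -> PSSM:
    """Profile from aligned member rows in seed coordinates.

    ``matches`` are gapped rows of length ``len(seed_seq)`` (the member set,
    typically including the seed itself); with no matches the profile falls
    back to the seed alone.  Per column, weighted residue counts (gaps
    excluded) are blended with the background:

        freq[a] = (count[a] + w * bg[a]) / (n_nongap + w)

    and score[a] = log2(freq[a] / bg[a]).
    """
    if not seed_seq:
        raise ValueError("seed sequence must be nonempty")
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be > 0")
    _validate_protein(seed_seq, "seed")
    bg = EQUILIBRIUM_FREQS if background is None else np.asarray(background, float)
    rows = list(matches) if matches else [seed_seq]
    plen = len(seed_seq)
    for row in rows:
        if len(row) != plen:
            raise ValueError("match rows must have the seed's length")
    if weighting == "henikoff":
        w = _henikoff_weights(rows)
    elif weighting == "none":
        w = np.ones(len(rows))
    else:
        raise ValueError("weighting must be 'henikoff' or 'none'")

    counts = np.zeros((plen, 20))
    denom = np.zeros(plen)
    for row, wt in zip(rows, w):
        for p, c in enumerate(row):
            if c == "-":
                continue
            counts[p, AA_INDEX[c]] += wt
            denom[p] += wt
    freqs = (counts + pseudocount_weight * bg[None, :]) / (
        denom[:, None] + pseudocount_weight
    )
    scores = np.log2(freqs / bg[None, :])
    return PSSM(source_id, seed_seq, scores, freqs, bg)


def _gumbel_params(sample_scores: np.ndarray) -> tuple[float, float]:
    """Moment fit of a Gumbel law (location, scale) to shuffled scores."""
    mean = float(sample_scores.mean())
    std = float(sample_scores.std())
    beta = max(std * math.sqrt(6.0) / math.pi, 1e-6)
    mu = mean - _EULER_GAMMA * beta
    return mu, beta


def _evalue(score: float, mu: float, beta: float, db_size: int) -> float:
    z = (score - mu) / beta
    # tail probability of the Gumbel law, numerically safe for large z
    if z > 40:
        p = math.exp(-z)
    else:
        p = 1.0 - math.exp(-math.exp(-z))
    return db_size * p


def gather_homologs(
    seed_seq: str,
    db: dict[str, str],
    seed_id: str = "query",
    max_iter: int = 6,
    evalue_cut: float = 1e-6,
    pseudocount_weight: float = 1.0,
    weighting: str = "henikoff",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    n_shuffles: int = 12,
    seed: int = 0,
) -> dict[str, str]:
    """Iteratively gather database members into the seed's profile.

    Returns member rows aligned to seed coordinates ('-' for unaligned
    positions), seed first.  The member set only ever grows, so gathering
    is monotone across iterations; it stops at convergence or ``max_iter``.
    """
    from .align import _sw_kernel, encode_sequence  # local import, no cycle

    if not seed_seq:
        raise ValueError("seed sequence must be nonempty")
    _validate_protein(seed_seq, "seed")
    for name, s in db.items():
        _validate_protein(s, name)

    rng = np.random.default_rng(seed)
    members: dict[str, str] = {seed_id: seed_seq}
    db_items = [(k, v) for k, v in db.items() if k != seed_id]
    encoded = {k: encode_sequence(v) for k, v in db_items}
    plen = len(seed_seq)

    for _ in range(max_iter):
        pssm = build_pssm(
            seed_seq,
            list(members.values()),
            pseudocount_weight=pseudocount_weight,
            weighting=weighting,
            source_id=seed_id,
        )
        scores_arr = np.ascontiguousarray(pssm.scores)

        # calibrate the e-value law on shuffled database sequences
        sample = []
        pool = db_items if db_items else [(seed_id, seed_seq)]
        for k in range(n_shuffles):
            _, s = pool[k % len(pool)]
            letters = np.array(list(s))
            rng.shuffle(letters)
            sidx = encode_sequence("".join(letters))
            sc, _, _, _, _ = _sw_kernel(scores_arr, sidx,
                                        float(gap_open), float(gap_extend))
            sample.append(sc)
        mu, beta = _gumbel_params(np.array(sample))

        added = False
        for name, _ in db_items:
            if name in members:
                continue
            sc, ops, n_ops, end_i, end_j = _sw_kernel(
                scores_arr, encoded[name], float(gap_open), float(gap_extend)
            )
            if sc <= 0 or n_ops == 0:
                continue
            if _evalue(float(sc), mu, beta, max(len(db_items), 1)) > evalue_cut:
                continue
            row = ["-"] * plen
            qidx = encoded[name]
            i, j = end_i, end_j
            for op in ops:  # ops run from the alignment end backwards
                if op == 0:  # residue vs profile position
                    row[j - 1] = ALPHABET[qidx[i - 1]]
                    i -= 1
                    j -= 1
                elif op == 1:  # gap in member
                    j -= 1
                else:  # insertion relative to the profile: dropped
                    i -= 1
            members[name] = "".join(row)
            added = True
        if not added:
            break
    return members


def build_library(
    queries: dict[str, str],
    db: dict[str, str] | None = None,
    max_iter: int = 6,
    evalue_cut: float = 1e-6,
    pseudocount_weight: float = 1.0,
    weighting: str = "henikoff",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    n_shuffles: int = 12,
    seed: int = 0,
) -> PSSMLibrary:
    """One gathered PSSM per query, in query order.

    ``db`` defaults to the query set itself.
    """
    if not queries:
        raise ValueError("queries must be nonempty")
    ids = list(queries)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate query ids")
    if db is None:
        db = dict(queries)
    pssms = []
    for k, (qid, seq) in enumerate(queries.items()):
        members = gather_homologs(
            seq,
            db,
            seed_id=qid,
            max_iter=max_iter,
            evalue_cut=evalue_cut,
            pseudocount_weight=pseudocount_weight,
            weighting=weighting,
            gap_open=gap_open,
            gap_extend=gap_extend,
            n_shuffles=n_shuffles,
            seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)),
        )
        pssms.append(
            build_pssm(
                seq,
                list(members.values()),
                pseudocount_weight=pseudocount_weight,
                weighting=weighting,
                background=None,
                source_id=qid,
            )
        )
    metadata = {
        "max_iter": max_iter,
        "evalue_cut": evalue_cut,
        "pseudocount_weight": pseudocount_weight,
        "weighting": weighting,
        "gap_open": gap_open,
        "gap_extend": gap_extend,
        "n_shuffles": n_shuffles,
        "seed": seed,
        "db_size": len(db),
    }
    return PSSMLibrary(pssms, metadata)
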