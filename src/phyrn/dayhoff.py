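"""Dayhoff (1978) amino-acid substitution model: the PAM family.

The PAM (point accepted mutation) model is an empirical Markov model of
amino-acid replacement.  One PAM unit corresponds to an expected 0.01
accepted substitutions per site.  The PAM-*d* transition matrix is the
PAM-1 matrix raised to the *d*-th power; this module computes those powers
spectrally (the model is time-reversible, so the generator can be
symmetrized and diagonalized with a real orthogonal eigenbasis).

Constants are the standard Dayhoff exchangeabilities and equilibrium
frequencies (``dayhoff.dat`` convention, residue order
``ARNDCQEGHILKMFPSTWYV``).
"""

from __future__ import annotations

import functools

import numpy as np

#: Residue order used throughout the package (PAML / dayhoff.dat order).
ALPHABET = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Lower triangle (row > col) of the symmetric exchangeability matrix.
_EXCHANGE_LOWER = np.array([
    27, 98, 120, 36,
    89, 198, 240, 23,
    65, 41, 26, 72,
    18, 250, 409, 371,
    0, 24, 208, 32,
    0, 23, 246, 1,
    9, 240, 64, 15,
    464, 90, 14, 103,
    154, 26, 201, 8,
    24, 905, 0, 103,
    148, 139, 535, 77,
    34, 318, 1, 14,
    42, 495, 229, 23,
    95, 15, 0, 134,
    1153, 125, 86, 24,
    0, 71, 0, 0,
    13, 95, 66, 0,
    0, 18, 0, 0,
    11, 28, 44, 0,
    0, 0, 0, 19,
    161, 16, 0, 96,
    49, 716, 28, 606,
    18, 73, 153, 114,
    0, 153, 56, 53,
    0, 0, 35, 81,
    43, 61, 11, 83,
    30, 0, 51, 79,
    34, 0, 22, 37,
    10, 0, 7, 27,
    17, 15, 34, 234,
    30, 0, 0, 54,
    7, 44, 26, 0,
    48, 94, 35, 22,
    27, 127, 44, 257,
    46, 336, 196, 12,
    24, 192, 0, 37,
    889, 18, 527, 157,
    32, 17, 33, 46,
    28, 175, 243, 0,
    33, 96, 136, 0,
    13, 10, 92, 17,
    62, 104, 0, 0,
    258, 11, 46, 13,
    76, 698, 12, 245,
    78, 0, 0, 48,
    550, 75, 34, 30,
    0, 42, 157, 61,
    0, 28,
])

#: Dayhoff equilibrium amino-acid frequencies (sum to 1).
EQUILIBRIUM_FREQS = np.array([
    0.0871269128730871, 0.0409039590960409, 0.0404319595680404, 0.0468719531280469,
    0.0334739665260335, 0.0382549617450383, 0.0495299504700495, 0.0886119113880886,
    0.0336179663820336, 0.0368859631140369, 0.0853569146430854, 0.0804819195180805,
    0.0147529852470148, 0.0397719602280398, 0.0506799493200507, 0.0695769304230696,
    0.0585419414580585, 0.0104939895060105, 0.0299159700840299, 0.0647179352820647,
])
EQUILIBRIUM_FREQS = EQUILIBRIUM_FREQS / EQUILIBRIUM_FREQS.sum()

def _rate_matrix() -> np.ndarray:
    """Dayhoff generator scaled so one time unit = 1 PAM (0.01 subs/site)."""
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = _EXCHANGE_LOWER[k]
            k += 1
    rate = s * EQUILIBRIUM_FREQS[None, :]
    np.fill_diagonal(rate, 0.0)
    np.fill_diagonal(rate, -rate.sum(axis=1))
    mean_rate = -(EQUILIBRIUM_FREQS * np.diag(rate)).sum()
    return rate * (0.01 / mean_rate)


@functools.lru_cache(maxsize=1)
def _spectral() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rate = _rate_matrix()
    sqrt_pi = np.sqrt(EQUILIBRIUM_FREQS)
    sym = sqrt_pi[:, None] * rate / sqrt_pi[None, :]
    eigvals, eigvecs = np.linalg.eigh((sym + sym.T) / 2.0)
    return eigvals, eigvecs, sqrt_pi


@functools.lru_cache(maxsize=4096)
def transition_matrix(pam: int) -> np.ndarray:
    """PAM-``pam`` substitution probability matrix (PAM-1 to the ``pam``-th power).

    Rows index the ancestral residue, columns the descendant residue; each
    row sums to 1.  The result is cached per integer distance.
    """
    if pam < 0:
        raise ValueError("PAM distance must be non-negative")
    eigvals, eigvecs, sqrt_pi = _spectral()
    scaled = (eigvecs * np.exp(eigvals * pam)) @ eigvecs.T
    prob = scaled / sqrt_pi[:, None] * sqrt_pi[None, :]
    prob = np.clip(prob, 0.0, None)
    prob /= prob.sum(axis=1, keepdims=True)
    prob.setflags(write=False)
    return prob


def expected_identity(pam: float) -> float:
    """Expected fraction of identical sites between two sequences whose
    total path length on the tree is ``pam`` PAM units (no indels)."""
    prob = transition_matrix(int(round(pam)))
    return float((EQUILIBRIUM_FREQS * np.diag(prob)).sum())
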