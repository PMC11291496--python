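"""Random-matrix-theory machinery for correlation thresholding.

A correlation matrix dominated by genuine associations has eigenvalue
nearest-neighbour spacings that repel (Wigner/GOE statistics); once the
noise correlations are zeroed out, the surviving structure decomposes into
effectively independent blocks and the spacings become Poisson (exponential).
The threshold scan looks for the transition point.

Unfolding is local: each spacing is divided by the mean spacing of a small
moving window, which removes the global density profile without assuming a
functional form. Conformity is judged by a chi-square goodness-of-fit of the
spacing histogram (bins of 0.1 on [0, 3], open tail) against the exponential
or the Wigner surmise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

#: minimum distinct eigenvalues for a meaningful spacing distribution
MIN_EIGENVALUES = 20


def unfolded_spacings(eigenvalues: np.ndarray, window: int = 5, tol: float = 1e-8) -> np.ndarray:
    """Nearest-neighbour spacings of a locally unfolded spectrum, mean 1.

    Degenerate eigenvalues (within ``tol``) are collapsed first; thresholded
    correlation matrices produce large degenerate spikes (e.g. isolated rows
    contributing eigenvalue exactly 1) that carry no spacing information.
    """
    e = np.sort(np.asarray(eigenvalues, float))
    e = e[np.concatenate([[True], np.diff(e) > tol])]
    if len(e) < MIN_EIGENVALUES:
        raise ValueError(f"need >= {MIN_EIGENVALUES} distinct eigenvalues, got {len(e)}")
    d = np.diff(e)
    k = 2 * window + 1
    pad = np.concatenate([d[:window][::-1], d, d[-window:][::-1]])
    local_mean = np.convolve(pad, np.ones(k) / k, mode="valid")
    s = d / local_mean
    return s / s.mean()


def _spacing_cdf(dist: str):
    if dist == "poisson":
        return lambda x: 1.0 - np.exp(-x)
    if dist == "wigner":
        return lambda x: 1.0 - np.exp(-np.pi * x**2 / 4.0)
    raise ValueError(f"unknown spacing distribution {dist!r}")


def spacing_gof(
    spacings: np.ndarray,
    dist: str,
    bin_width: float = 0.1,
    s_max: float = 3.0,
    min_expected: float = 5.0,
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of spacings against ``dist``.

    Returns (chi2 per degree of freedom, p-value). Bins with expected count
    below ``min_expected`` are merged rightward; mass beyond ``s_max`` goes
    into an open tail bin.
    """
    s = np.asarray(spacings, float)
    edges = np.arange(0.0, s_max + bin_width / 2, bin_width)
    obs = np.histogram(s, bins=edges)[0].astype(float)
    obs[-1] += np.sum(s >= s_max)
    cdf = _spacing_cdf(dist)
    prob = np.diff(cdf(edges))
    prob[-1] += 1.0 - cdf(edges[-1])
    exp = prob * len(s)
    merged_o, merged_e = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            merged_o.append(acc_o)
            merged_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and merged_e:
        merged_o[-1] += acc_o
        merged_e[-1] += acc_e
    o_arr, e_arr = np.array(merged_o), np.array(merged_e)
    stat = float(np.sum((o_arr - e_arr) ** 2 / e_arr))
    dof = max(len(o_arr) - 1, 1)
    return stat / dof, float(sps.chi2.sf(stat, dof))


def classify_spacings(spacings: np.ndarray) -> tuple[str, float, float]:
    """Label a spacing sample 'poisson' or 'wigner' by the smaller reduced
    chi-square; returns (label, p_poisson, p_wigner)."""
    chi_p, p_p = spacing_gof(spacings, "poisson")
    chi_w, p_w = spacing_gof(spacings, "wigner")
    return ("poisson" if chi_p <= chi_w else "wigner", p_p, p_w)


def nnsd_poisson_pvalue(eigenvalues: np.ndarray) -> float:
    """Convenience: p-value of the Poisson GOF on an eigenvalue spectrum."""
    return spacing_gof(unfolded_spacings(eigenvalues), "poisson")[1]


# -- simulators used for classifier validation ------------------------------


def goe_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian orthogonal ensemble draw (symmetrised standard normal)."""
    m = rng.normal(size=(n, n))
    return (m + m.T) / 2.0


def block_diagonal_correlation(
    n_blocks: int,
    block_size: int,
    rng: np.random.Generator,
    rho_range: tuple[float, float] = (0.4, 0.8),
    n_obs: int = 30,
) -> np.ndarray:
    """Sample correlation matrix of independent equicorrelated blocks.

    Its eigenvalues are a superposition of independent block spectra, so the
    spacing statistics are Poisson — the post-threshold reference case.
    """
    mats = []
    for _ in range(n_blocks):
        rho = rng.uniform(*rho_range)
        cov = np.full((block_size, block_size), rho)
        np.fill_diagonal(cov, 1.0)
        x = rng.multivariate_normal(np.zeros(block_size), cov, size=n_obs)
        mats.append(np.corrcoef(x.T))
    out = np.zeros((n_blocks * block_size, n_blocks * block_size))
    for i, m in enumerate(mats):
        sl = slice(i * block_size, (i + 1) * block_size)
        out[sl, sl] = m
    return out
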