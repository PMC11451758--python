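"""Pairwise linkage-disequilibrium statistics.

D = pAB - pA*pB; D' normalizes D by its frequency-constrained maximum
(sign-dependent); R^2 is the squared allelic correlation. From phased
haplotypes the statistics are plug-in; from unphased genotypes the four
haplotype frequencies are estimated by EM over the double-heterozygote
phase ambiguity, started at linkage equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DataError

__all__ = ["LDResult", "ld_from_haplotypes", "em_haplotype_freqs"]


class MonomorphicError(DataError):
    """LD is undefined when a locus is monomorphic."""


@dataclass
class LDResult:
    """Haplotype frequencies and the derived LD statistics for one pair."""

    pAB: float
    pAb: float
    paB: float
    pab: float
    D: float
    d_prime: float
    r2: float
    method: str  # "phased" or "em"
    n: int
    converged: bool = True
    iterations: int = 0
    loglik_path: list[float] | None = None

    @property
    def pA(self) -> float:
        return self.pAB + self.pAb

    @property
    def pB(self) -> float:
        return self.pAB + self.paB


def _ld_stats(freqs: np.ndarray) -> tuple[float, float, float]:
    pAB, pAb, paB, pab = freqs
    pA = pAB + pAb
    pB = pAB + paB
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if dmax == 0 else D / dmax
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom == 0 else D * D / denom
    return float(D), float(d_prime), float(r2)


def ld_from_haplotypes(nAB: float, nAb: float, naB: float, nab: float) -> LDResult:
    """Plug-in LD statistics from the four phased haplotype counts."""
    counts = np.asarray([nAB, nAb, naB, nab], dtype=float)
    if np.any(counts < 0):
        raise DataError("haplotype counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise DataError("total haplotype count must be positive")
    freqs = counts / total
    pA, pB = freqs[0] + freqs[1], freqs[0] + freqs[2]
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicError("LD undefined: a locus is monomorphic")
    D, d_prime, r2 = _ld_stats(freqs)
    return LDResult(*freqs, D, d_prime, r2, method="phased", n=int(total))


def em_haplotype_freqs(
    g1, g2, tol: float = 1e-10, maxiter: int = 1000
) -> LDResult:
    """EM haplotype-frequency estimation from unphased dosages.

    Only the double heterozygote (1,1) is phase-ambiguous: it contributes
    either AB+ab or Ab+aB. The E-step splits those individuals by the
    current odds pAB*pab : pAb*paB; the M-step re-normalizes expected
    haplotype counts. Iterates from linkage-equilibrium frequencies until
    the largest absolute frequency change is below ``tol``.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = np.isfinite(g1) & np.isfinite(g2)
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    if n == 0:
        raise DataError("no complete genotype pairs")
    if g1.std() == 0 or g2.std() == 0:
        raise MonomorphicError("LD undefined: a locus is monomorphic")

    # 3x3 genotype table
    table = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            table[a, b] = np.sum((g1 == a) & (g2 == b))

    # fixed haplotype contributions from phase-unambiguous cells
    # (A allele count toward hap class) for each cell except (1,1)
    fixed = np.zeros(4)  # nAB, nAb, naB, nab
    contrib = {
        (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
    }
    for cell, c in contrib.items():
        fixed += table[cell] * np.asarray(c, dtype=float)
    n_dh = table[1, 1]

    # alt-allele count at each locus for the four haplotype classes
    hap_a = np.array([1, 1, 0, 0])
    hap_b = np.array([1, 0, 1, 0])

    def loglik(freqs: np.ndarray) -> float:
        probs = np.zeros((3, 3))
        for i in range(4):
            for j in range(4):
                probs[hap_a[i] + hap_a[j], hap_b[i] + hap_b[j]] += freqs[i] * freqs[j]
        mask = table > 0
        return float(np.sum(table[mask] * np.log(probs[mask])))

    pA = g1.mean() / 2.0
    pB = g2.mean() / 2.0
    freqs = np.array(
        [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)]
    )
    loglik_path = [loglik(freqs)]
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        pAB, pAb, paB, pab = freqs
        cis = pAB * pab
        trans = pAb * paB
        w = 0.5 if cis + trans == 0 else cis / (cis + trans)
        counts = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
        new_freqs = counts / (2.0 * n)
        loglik_path.append(loglik(new_freqs))
        if np.max(np.abs(new_freqs - freqs)) < tol:
            freqs = new_freqs
            converged = True
            break
        freqs = new_freqs
    D, d_prime, r2 = _ld_stats(freqs)
    return LDResult(
        *freqs, D, d_prime, r2, method="em", n=n,
        converged=converged, iterations=it, loglik_path=loglik_path,
    )
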