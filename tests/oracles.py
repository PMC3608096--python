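"""Independent oracles for the exact computations.

Everything here is written from first principles, separately from the
package implementation: the two-locus pedigree likelihood by exhaustive
enumeration of ordered genotype configurations, and the 3×2 exact
conditional test by filtering the full table lattice with the factorial
probability formula.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import factorial

import numpy as np

MISSING = -1

# haplotype h = (d, m) encoded 2*d + m; ordered genotype g = 4*h_pat + h_mat
_HAPS = [(d, m) for d in (0, 1) for m in (0, 1)]


def _transmit_prob(parent_g: int, hap: int, theta: float) -> float:
    """P(parent transmits haplotype hap), summed over strand choice and
    recombination events — derived directly from the meiosis model."""
    hp, hm = divmod(parent_g, 4)
    (d_p, m_p), (d_m, m_m) = _HAPS[hp], _HAPS[hm]
    d, m = _HAPS[hap]
    p = 0.0
    for d_start, m_same, m_other in ((d_p, m_p, m_m), (d_m, m_m, m_p)):
        if d == d_start:
            p += 0.5 * ((1.0 - theta) * (m == m_same) + theta * (m == m_other))
    return p


def brute_force_loglik(
    ped,
    dosages: dict[str, int],
    marker_freq: float,
    penetrance: tuple[float, float, float],
    disease_freq: float,
    theta: float,
    max_configs: int = 4_000_000,
) -> float:
    """log-likelihood by exhaustive enumeration over ordered genotypes.

    Enumerates, for every pedigree member, all 16 ordered two-locus
    genotypes consistent with the observed marker dosage, and sums the
    product of founder priors, transmission probabilities and penetrance
    factors over the full cartesian grid (vectorized).
    """
    members = list(ped.individuals)
    n = len(members)
    q, p_alt = disease_freq, marker_freq
    hap_prior = np.array([(q if d else 1 - q) * (p_alt if m else 1 - p_alt) for d, m in _HAPS])
    g_prior = np.array([hap_prior[g // 4] * hap_prior[g % 4] for g in range(16)])
    m_count = np.array([_HAPS[g // 4][1] + _HAPS[g % 4][1] for g in range(16)])
    d_count = np.array([_HAPS[g // 4][0] + _HAPS[g % 4][0] for g in range(16)])
    pen = np.asarray(penetrance)

    allowed = []
    for ind in members:
        d = dosages.get(ind.id, MISSING)
        allowed.append(list(range(16)) if d == MISSING else [g for g in range(16) if m_count[g] == d])
    size = np.prod([len(a) for a in allowed])
    if size > max_configs:
        raise ValueError(f"brute-force space too large: {size}")

    grids = np.meshgrid(*[np.array(a) for a in allowed], indexing="ij")
    conf = np.stack([g.ravel() for g in grids], axis=1)  # (K, n)

    T = np.array([[_transmit_prob(g, h, theta) for h in range(4)] for g in range(16)])
    prob = np.ones(conf.shape[0])
    idx = {ind.id: k for k, ind in enumerate(members)}
    for k, ind in enumerate(members):
        g = conf[:, k]
        if ind.is_founder:
            prob *= g_prior[g]
        else:
            gf = conf[:, idx[ind.father_id]]
            gm = conf[:, idx[ind.mother_id]]
            prob *= T[gf, g // 4] * T[gm, g % 4]
        if ind.affection == "affected":
            prob *= pen[d_count[g]]
        elif ind.affection == "unaffected":
            prob *= 1.0 - pen[d_count[g]]
    total = prob.sum()
    return float(np.log(total)) if total > 0 else float("-inf")


def fisher_3x2_oracle(table) -> Fraction:
    """Exact conditional 3×2 test by full lattice enumeration.

    Generates every non-negative integer table, keeps those matching the
    observed margins, scores each with the factorial formula
    P = (∏ rows! ∏ cols!) / (N! ∏ cells!), and sums the probabilities not
    exceeding the observed table's.
    """
    t = [[int(x) for x in row] for row in table]
    rows = [sum(r) for r in t]
    cols = [sum(t[i][j] for i in range(3)) for j in range(2)]
    n = sum(rows)
    if n == 0:
        return Fraction(1)
    margin_const = Fraction(
        factorial(rows[0]) * factorial(rows[1]) * factorial(rows[2])
        * factorial(cols[0]) * factorial(cols[1]),
        factorial(n),
    )

    def prob(cells: list[int]) -> Fraction:
        denom = 1
        for c in cells:
            denom *= factorial(c)
        return margin_const / denom

    obs = prob([t[i][j] for i in range(3) for j in range(2)])
    total = Fraction(0)
    ranges = [range(min(rows[i], cols[j]) + 1) for i in range(3) for j in range(2)]
    for cells in itertools.product(*ranges):
        if (
            cells[0] + cells[1] == rows[0]
            and cells[2] + cells[3] == rows[1]
            and cells[4] + cells[5] == rows[2]
            and cells[0] + cells[2] + cells[4] == cols[0]
            and cells[1] + cells[3] + cells[5] == cols[1]
        ):
            pr = prob(list(cells))
            if pr <= obs:
                total += pr
    return total


def random_linkage_instance(rng: np.random.Generator):
    """Random small pedigree + marker + model for oracle comparison.

    Keeps the enumeration space manageable by bounding pedigree size at 8
    and keeping missingness low.
    """
    from famphase.pedigree import Individual, Pedigree

    layout = rng.choice(["trio", "quartet", "nuclear6", "threegen"])
    inds = [Individual("F", sex="male", affection=_rand_aff(rng)),
            Individual("M", sex="female", affection=_rand_aff(rng))]
    if layout == "trio":
        kids = 1
    elif layout == "quartet":
        kids = 2
    elif layout == "nuclear6":
        kids = 4
    else:
        kids = 3
    for k in range(kids):
        inds.append(Individual(f"C{k}", "F", "M", "unknown", _rand_aff(rng)))
    if layout == "threegen":
        inds.append(Individual("S", sex="male", affection=_rand_aff(rng)))
        for k in range(2):
            inds.append(Individual(f"G{k}", "S", "C0", "unknown", _rand_aff(rng)))
    ped = Pedigree(inds)

    if rng.random() < 0.8:
        # Mendelian-consistent pattern from a miniature gene drop
        hap: dict[str, tuple[int, int]] = {}
        for ind in ped:
            if ind.is_founder:
                hap[ind.id] = (int(rng.random() < 0.5), int(rng.random() < 0.5))
            else:
                hap[ind.id] = (
                    hap[ind.father_id][int(rng.integers(0, 2))],
                    hap[ind.mother_id][int(rng.integers(0, 2))],
                )
        dosages = {i: (MISSING if rng.random() < 0.12 else sum(hap[i])) for i in ped.ids}
    else:
        dosages = {
            i: (MISSING if rng.random() < 0.12 else int(rng.integers(0, 3))) for i in ped.ids
        }
    if all(v == MISSING for v in dosages.values()):
        dosages[ped.ids[0]] = int(rng.integers(0, 3))
    # keep the enumeration grid tractable: missing=16, het=8, hom=4 states
    states = {MISSING: 16, 1: 8, 0: 4, 2: 4}
    while np.prod([states[dosages[i]] for i in ped.ids]) > 1_500_000:
        widest = max(ped.ids, key=lambda i: states[dosages[i]])
        dosages[widest] = int(rng.choice([0, 2]))
    freq = float(rng.uniform(0.1, 0.9))
    pen = tuple(sorted(rng.uniform(0, 1, size=3)))
    q = float(10 ** rng.uniform(-5, -1))
    theta = float(rng.choice([0.0, 0.1, 0.5]))
    return ped, dosages, freq, pen, q, theta


def _rand_aff(rng) -> str:
    return str(rng.choice(["affected", "unaffected", "unknown"], p=[0.35, 0.45, 0.2]))
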