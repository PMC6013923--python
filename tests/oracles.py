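"""Independent oracles for the test suite.

Everything here is deliberately written without using mitoflux's own
computational paths: beta-oxidation is enumerated cycle by cycle from
explicit double-bond positions, ATP yields are summed spreadsheet-style
from pathway cofactor counts and the documented proton stoichiometry,
dead ends are found by explicit producer/consumer sets, and quantiles
are computed by a second, sort-based implementation.
"""

from __future__ import annotations

import numpy as np

# Delta positions of the double bonds in the dietary unsaturated species.
DOUBLE_BOND_POSITIONS = {
    (18, 1): [9],
    (18, 2): [9, 12],
    (18, 3): [9, 12, 15],
    (20, 5): [5, 8, 11, 14, 17],
    (22, 6): [4, 7, 10, 13, 16, 19],
}


def enumerate_beta_oxidation(carbons: int, double_bonds: int):
    """Cycle-by-cycle enumeration of matrix beta-oxidation.

    Walks the acyl chain two carbons at a time; a cycle whose proximal
    double bond has reached position 2 or 3 consumes it via the
    isomerase route and skips the FAD-dependent dehydrogenation.
    Returns (acetyl_coa, nadh, fadh2, cycles).
    """
    if carbons % 2:
        raise ValueError("odd chain")
    bonds = sorted(DOUBLE_BOND_POSITIONS.get((carbons, double_bonds),
                                             list(range(3, 3 + 3 * double_bonds, 3))))
    assert len(bonds) == double_bonds
    acetyl = nadh = fadh2 = cycles = 0
    remaining = carbons
    while remaining > 2:
        if bonds and bonds[0] <= 3:
            bonds.pop(0)  # isomerase consumes the bond; no FAD step
        else:
            fadh2 += 1
        nadh += 1
        acetyl += 1
        cycles += 1
        remaining -= 2
        bonds = [b - 2 for b in bonds]
    acetyl += 1  # the final C4 thiolysis releases two acetyl-CoA in total
    return acetyl, nadh, fadh2, cycles


# --- ATP yield accounting under the documented proton stoichiometry ------
# 10 H+ pumped per matrix NADH (complexes I+III+IV: 4+4+2), 6 per
# FADH2-level quinol (III+IV), effective cost 4 H+ per ATP delivered to
# the cytosol; substrate-level ATP is added directly.

H_PER_NADH = 10
H_PER_QH2 = 6
H_PER_ATP = 4


def _oxidative_atp(nadh_m: float, qh2: float) -> float:
    return (H_PER_NADH * nadh_m + H_PER_QH2 * qh2) / H_PER_ATP


def atp_per_acetyl_coa() -> tuple[float, float, float]:
    """(NADH_m, QH2, substrate-level ATP) per acetyl-CoA through the TCA cycle."""
    return 3.0, 1.0, 1.0


def atp_yield_glucose() -> float:
    """Max ATP per glucose: glycolysis + shuttle + PDH + TCA + ETC."""
    nadh_m = 2.0  # 2 cytosolic NADH via malate-aspartate shuttle
    nadh_m += 2.0  # PDH on both pyruvates
    tca_n, tca_q, tca_slp = atp_per_acetyl_coa()
    nadh_m += 2 * tca_n
    qh2 = 2 * tca_q
    slp = 2.0 + 2 * tca_slp  # glycolytic + succinyl-CoA synthetase
    return _oxidative_atp(nadh_m, qh2) + slp


def atp_yield_glucose_anaerobic() -> float:
    """No oxygen: glycolysis with lactate fermentation only."""
    return 2.0


def atp_yield_fatty_acid(carbons: int, double_bonds: int) -> float:
    """Max ATP per free fatty acid (activation costs two ATP equivalents)."""
    acetyl, box_nadh, box_fadh2, _ = enumerate_beta_oxidation(carbons, double_bonds)
    tca_n, tca_q, tca_slp = atp_per_acetyl_coa()
    nadh_m = box_nadh + acetyl * tca_n
    qh2 = box_fadh2 + acetyl * tca_q
    slp = acetyl * tca_slp - 2.0  # ATP -> AMP activation
    return _oxidative_atp(nadh_m, qh2) + slp


def atp_yield_glycerol() -> float:
    """Glycerol kinase, cytosolic oxidation to pyruvate, full oxidation."""
    # kinase -1 ATP; G3PD1 + lower glycolysis: 2 cytosolic NADH (shuttled),
    # +2 ATP; pyruvate: PDH NADH + one TCA turn
    tca_n, tca_q, tca_slp = atp_per_acetyl_coa()
    nadh_m = 2.0 + 1.0 + tca_n
    qh2 = tca_q
    slp = -1.0 + 2.0 + tca_slp
    return _oxidative_atp(nadh_m, qh2) + slp


def atp_yield_tag(carbons: int, double_bonds: int) -> float:
    """Max ATP per uniform triacylglyceride (three acyls + the glycerol)."""
    return 3 * atp_yield_fatty_acid(carbons, double_bonds) + atp_yield_glycerol()


# --- structural oracles ---------------------------------------------------


def brute_force_dead_ends(model) -> list[str]:
    """Explicit producer/consumer sets per metabolite."""
    out = []
    for met in model.metabolite_ids:
        produced = consumed = False
        for rxn in model.reactions:
            coef = rxn.stoichiometry.get(met)
            if coef is None:
                continue
            if rxn.upper_bound > 0:
                produced |= coef > 0
                consumed |= coef < 0
            if rxn.lower_bound < 0:
                produced |= coef < 0
                consumed |= coef > 0
        if not (produced and consumed):
            out.append(met)
    return out


def quantiles_sorted(x, qs=(0.25, 0.5, 0.75)):
    """Type-7 (linear interpolation) quantiles via explicit sorting."""
    xs = sorted(float(v) for v in x)
    n = len(xs)
    out = []
    for q in qs:
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        frac = pos - lo
        out.append(xs[lo] * (1 - frac) + xs[hi] * frac)
    return out


def rejection_sample_toy(lb, ub, coupling, n, rng):
    """Uniform points in {x in box : coupling @ x <= 1} by rejection."""
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    coupling = np.asarray(coupling, float)
    out = []
    while len(out) < n:
        x = rng.uniform(lb, ub, size=(4 * n, len(lb)))
        keep = x[(x @ coupling) <= 1.0]
        out.extend(keep.tolist())
    return np.array(out[:n])
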