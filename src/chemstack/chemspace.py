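"""Chemical-space diagnostics for train/test dataset audits.

Quantifies (i) drug-likeness of each class via the Lipinski rule-of-five
and Veber criteria, (ii) class-wise property differences via the
Mann–Whitney U test, (iii) scaffold novelty of the independent test set
(fraction of Bemis–Murcko scaffolds absent from training), and
(iv) structural overlap via the full train×test ECFP4 Tanimoto matrix.
A test set dominated by training scaffolds or high Tanimoto pairs
overstates generalization; these audits make that visible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import mannwhitneyu

from .errors import InputError
from .featurize import PhyschemProfile, ecfp4, murcko_scaffold

PHYSCHEM_PROPERTIES = ("mw", "alogp", "hba", "hbd", "tpsa", "nrotb")


def rule_flags(p: PhyschemProfile) -> tuple[bool, bool]:
    """Lipinski rule-of-five and Veber flags, strict inequalities.

    Ro5: AlogP < 5, MW < 500 Da, HBD < 5, HBA < 10.
    Veber: nRotB < 10, TPSA < 140 Å².
    """
    ro5 = p.alogp < 5 and p.mw < 500 and p.hbd < 5 and p.hba < 10
    veber = p.nrotb < 10 and p.tpsa < 140
    return ro5, veber


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test with midrank ties.

    Returns (U for group A, two-sided p).  Exact null distribution when
    the smaller group has ≤ 8 members and there are no ties; normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    method = "exact" if min(a.size, b.size) <= 8 else "asymptotic"
    try:
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; fall back to the tie-corrected normal
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def scaffold_uniqueness(train_smiles, test_smiles) -> float:
    """Fraction of distinct test-set scaffolds absent from the train set.

    Duplicate molecules within either split do not change the result:
    the computation is over distinct scaffold keys.
    """
    if not len(test_smiles):
        raise InputError("test set is empty")
    train_keys = {murcko_scaffold(s) for s in train_smiles}
    test_keys = {murcko_scaffold(s) for s in test_smiles}
    return len(test_keys - train_keys) / len(test_keys)


def tanimoto_audit(
    train_smiles, test_smiles, threshold: float = 0.5, n_bits: int = 2048
) -> tuple[float, float, np.ndarray]:
    """Score every train×test compound pair by ECFP4 Tanimoto similarity.

    Returns (mean similarity, fraction of pairs below ``threshold``,
    full train×test similarity matrix).
    """
    if not len(train_smiles) or not len(test_smiles):
        raise InputError("both compound sets must be non-empty")
    fps_a = np.array([ecfp4(s, n_bits) for s in train_smiles], dtype=bool)
    fps_b = np.array([ecfp4(s, n_bits) for s in test_smiles], dtype=bool)
    inter = fps_a.astype(np.int32) @ fps_b.astype(np.int32).T
    pop_a = fps_a.sum(axis=1, dtype=np.int32)[:, None]
    pop_b = fps_b.sum(axis=1, dtype=np.int32)[None, :]
    union = pop_a + pop_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return float(sim.mean()), float((sim < threshold).mean()), sim


@dataclass
class ChemSpaceReport:
    """Numeric summary of the chemical-space audit."""

    property_summary: dict      # property -> class -> {median, iqr, min, max}
    u_stats: dict               # property -> U
    p_values: dict              # property -> two-sided p
    ro5_pass_fraction: dict     # class -> fraction
    veber_pass_fraction: dict   # class -> fraction
    scaffold_unique_fraction: float
    tanimoto_mean: float
    tanimoto_below_half_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "median": float(med), "iqr": float(q3 - q1),
        "min": float(values.min()), "max": float(values.max()),
    }


def chemspace_report(
    train_active, train_inactive, test_smiles, threshold: float = 0.5
) -> ChemSpaceReport:
    """Full audit: property stats + tests, rule compliance, scaffold and
    Tanimoto overlap between training (both classes) and test sets."""
    from .featurize import compute_physchem

    prof_a = compute_physchem(train_active)
    prof_i = compute_physchem(train_inactive)
    prof_a = [p for p in prof_a if isinstance(p, PhyschemProfile)]
    prof_i = [p for p in prof_i if isinstance(p, PhyschemProfile)]
    if not prof_a or not prof_i:
        raise InputError("both classes need at least one parsable compound")

    property_summary, u_stats, p_values = {}, {}, {}
    for prop in PHYSCHEM_PROPERTIES:
        va = np.array([getattr(p, prop) for p in prof_a], dtype=float)
        vi = np.array([getattr(p, prop) for p in prof_i], dtype=float)
        property_summary[prop] = {"active": _summary(va), "inactive": _summary(vi)}
        u, pval = mann_whitney(va, vi)
        u_stats[prop], p_values[prop] = u, pval

    def _pass_fractions(profiles):
        flags = [rule_flags(p) for p in profiles]
        n = len(flags)
        return (sum(f[0] for f in flags) / n, sum(f[1] for f in flags) / n)

    ro5_a, veber_a = _pass_fractions(prof_a)
    ro5_i, veber_i = _pass_fractions(prof_i)
    train_all = list(train_active) + list(train_inactive)
    scaf = scaffold_uniqueness(train_all, test_smiles)
    mean_sim, below, _ = tanimoto_audit(train_all, test_smiles, threshold)
    return ChemSpaceReport(
        property_summary=property_summary,
        u_stats=u_stats,
        p_values=p_values,
        ro5_pass_fraction={"active": ro5_a, "inactive": ro5_i},
        veber_pass_fraction={"active": veber_a, "inactive": veber_i},
        scaffold_unique_fraction=scaf,
        tanimoto_mean=mean_sim,
        tanimoto_below_half_fraction=below,
    )
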