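"""Self-contained validation benchmarks for the stacking pipeline.

Each routine recomputes, from scratch and at desk scale, a structural or
statistical property the pipeline is built to guarantee: the default
configuration's counts (5 balanced subsets × 30 base models → a 150-wide
probability-feature matrix and 15 selection candidates), the descriptor
dimension contract, closed-form metric identities against brute-force
oracles, sampling invariants over random problem sizes, recovery of
planted informative features by the MDGI ranking, the benefit of the
stacked meta-classifier over its best base classifier on imbalanced
synthetic data, and end-to-end determinism.

These run the public package API only; they are what
``scripts/acceptance.py`` reports.
"""

from __future__ import annotations

import numpy as np

from .featurize import FAMILY_REGISTRY
from .metrics import ConfusionCounts, auc_score, compute_metrics, evaluate
from .sampling import auto_k, make_balanced_subsets
from .stack import (
    ALGORITHM_ORDER,
    FAMILY_ORDER,
    PFVMatrix,
    StackConfig,
    enumerate_keys,
    fit_stack,
)
from .synthetic import generate_block_dataset, generate_feature_dataset

#: the reference training-set class sizes the default configuration targets
REFERENCE_TRAIN_POS = 790
REFERENCE_TRAIN_NEG = 159


def _sub_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000 + salt) % (2**31 - 1))


def structural_constants() -> dict:
    """Counts implied by the default configuration at the reference scale."""
    subsets = make_balanced_subsets(
        list(range(REFERENCE_TRAIN_POS)), list(range(REFERENCE_TRAIN_NEG))
    )
    k = len(subsets)
    keys = enumerate_keys(ALGORITHM_ORDER, FAMILY_ORDER, k)
    width = PFVMatrix(
        matrix=np.zeros((1, len(keys))), columns=keys
    ).width
    selection_grid = list(range(10, width + 1, 10))
    return {
        "n_balanced_subsets": k,
        "majority_slice_size": len(subsets[0].majority_ids),
        "base_models_per_subset": len(keys) // k,
        "total_base_models": len(keys),
        "pfv_width": width,
        "n_selection_candidates": len(selection_grid),
    }


def descriptor_dimensions() -> dict:
    """Actual matrix widths produced for each registered family."""
    from .featurize import compute_descriptor_block

    probe = ["CC(=O)Oc1ccccc1C(=O)O", "c1ccncc1", "CCO"]
    return {
        fam.lower() + "_dim": compute_descriptor_block(probe, fam).matrix.shape[1]
        for fam in FAMILY_REGISTRY
    }


# --- metric identities against brute-force oracles -----------------------


def _pairwise_auc(y, s):
    wins = ties = total = 0
    for sp in s[y == 1]:
        for sn in s[y == 0]:
            total += 1
            wins += sp > sn
            ties += sp == sn
    return (wins + 0.5 * ties) / total


def metric_identity_errors(seed: int = 0, n_tables: int = 1000,
                           n_auc: int = 50) -> dict:
    """Max deviation from the defining identities over random inputs."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    bacc_err = anti_err = 0.0
    for _ in range(n_tables):
        tp, tn, fp, fn = rng.integers(0, 200, 4)
        if tp + tn + fp + fn == 0:
            continue
        r = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
        if r.sn is not None and r.sp is not None:
            bacc_err = max(bacc_err, abs(r.bacc - (r.sn + r.sp) / 2))
        swapped = compute_metrics(
            ConfusionCounts(int(fn), int(fp), int(tn), int(tp))
        )
        anti_err = max(anti_err, abs(r.mcc + swapped.mcc))
    auc_err = 0.0
    for _ in range(n_auc):
        n = int(rng.integers(6, 51))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            continue
        s = rng.choice(np.linspace(0, 1, 7), n)
        auc_err = max(auc_err, abs(auc_score(y, s) - _pairwise_auc(y, s)))
    return {
        "bacc_identity_max_error": float(bacc_err),
        "mcc_antisymmetry_max_error": float(anti_err),
        "auc_pairwise_max_error": float(auc_err),
    }


def sampling_invariant_violations(seed: int = 0, n_trials: int = 200) -> dict:
    """Count invariant breaches over random (n_maj, n_min, seed) triples."""
    rng = np.random.default_rng(_sub_seed(seed, 2))
    violations = 0
    for _ in range(n_trials):
        n_min = int(rng.integers(1, 60))
        n_maj = n_min + int(rng.integers(0, 300))
        s = int(rng.integers(0, 2**31 - 1))
        maj = list(range(n_maj))
        subs = make_balanced_subsets(maj, list(range(n_min)), seed=s)
        again = make_balanced_subsets(maj, list(range(n_min)), seed=s)
        sizes = [len(x.majority_ids) for x in subs]
        members = sorted(m for x in subs for m in x.majority_ids)
        ok = (
            members == maj                                   # coverage, disjoint
            and max(sizes) - min(sizes) <= 1                  # near-equal
            and [x.majority_ids for x in subs]
            == [x.majority_ids for x in again]                # deterministic
            and len(subs) == auto_k(n_maj, n_min)
        )
        violations += not ok
    return {"sampling_invariant_violations": violations, "n_trials": n_trials}


def feature_selection_recovery(seed: int = 0, n_seeds: int = 10,
                               n_pos: int = 600, n_neg: int = 120,
                               n_features: int = 150, n_informative: int = 10,
                               effect: float = 0.5, top: int = 20) -> dict:
    """MDGI recovery of planted informative columns, median over seeds."""
    from .stack import rank_pfs_mdgi

    hits = []
    for i in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 100 + i))
        X, y = generate_feature_dataset(
            n_pos, n_neg, n_features, n_informative, effect,
            seed=_sub_seed(seed, 200 + i),
        )
        perm = rng.permutation(n_features)
        informative = set(np.flatnonzero(np.isin(perm, range(n_informative))))
        pfv = PFVMatrix(
            X[:, perm].astype(float),
            enumerate_keys(("RF",), ("SYN",), n_features),
        )
        ranking, _ = rank_pfs_mdgi(pfv, y, seed=_sub_seed(seed, 300 + i))
        hits.append(len(informative & set(ranking[:top].tolist())))
    return {
        "fs_recovery_top20_median": float(np.median(hits)),
        "fs_recovery_per_seed": hits,
        "n_informative": n_informative,
    }


ENSEMBLE_BLOCKS = {"B1": (60, 8), "B2": (40, 6)}
ENSEMBLE_ALGORITHMS = ("KNN", "RF", "XGB")


def _subset_oof_mcc(base) -> dict:
    """Cross-validation MCC of each base model inside its own subset."""
    from .metrics import confusion

    out = {}
    for key, oof in base.oof.items():
        subset = base.subsets[key.subset_index - 1]
        y_sub = subset.labels
        preds = (oof >= 0.5).astype(int)
        out[key] = compute_metrics(confusion(y_sub, preds)).mcc
    return out


def ensemble_benefit(seed: int = 0, n_seeds: int = 10,
                     n_train=(300, 60), n_test=(150, 30),
                     effect: float = 0.35) -> dict:
    """Stacked meta-classifier vs its best base model on fresh test data.

    For each seed: train the scaled stack (3 algorithms × 2 descriptor
    blocks × 5 balanced subsets) on imbalanced synthetic data, pick the
    base model with the highest within-subset CV MCC (the selection rule
    a practitioner would use), and compare independent-test MCC of the
    stack against that base model.  Reports medians over seeds.
    """
    stacked, best_base, best_base_by_test = [], [], []
    for i in range(n_seeds):
        s = _sub_seed(seed, 400 + i)
        blocks, y = generate_block_dataset(*n_train, ENSEMBLE_BLOCKS, effect,
                                           seed=s)
        tblocks, ty = generate_block_dataset(*n_test, ENSEMBLE_BLOCKS, effect,
                                             seed=_sub_seed(seed, 500 + i))
        config = StackConfig(
            algorithms=ENSEMBLE_ALGORITHMS, families=tuple(ENSEMBLE_BLOCKS),
            k=5, base_folds=5, selection_folds=5, seed=s,
        )
        model, _ = fit_stack(blocks, y, config)
        stacked.append(evaluate(ty, model.predict_from_blocks(tblocks)).mcc)

        cv_mcc = _subset_oof_mcc(model.base)
        test_mcc = {}
        for key, est in model.base.models.items():
            proba = est.predict_proba(
                np.asarray(tblocks[key.descriptor_family], dtype=float)
            )[:, 1]
            test_mcc[key] = evaluate(ty, proba).mcc
        chosen = max(cv_mcc, key=cv_mcc.get)
        best_base.append(test_mcc[chosen])
        best_base_by_test.append(max(test_mcc.values()))
    return {
        "stacked_test_mcc_median": float(np.median(stacked)),
        "best_base_test_mcc_median": float(np.median(best_base)),
        "oracle_best_base_test_mcc_median": float(np.median(best_base_by_test)),
        "stacked_per_seed": stacked,
        "best_base_per_seed": best_base,
        "n_seeds": n_seeds,
    }


def determinism_check(seed: int = 0) -> dict:
    """Two identical runs must produce byte-identical metric JSON."""
    def one_run():
        blocks, y = generate_block_dataset(
            100, 20, {"B1": (25, 5), "B2": (20, 4)}, 0.5,
            seed=_sub_seed(seed, 600),
        )
        tb, ty = generate_block_dataset(
            50, 10, {"B1": (25, 5), "B2": (20, 4)}, 0.5,
            seed=_sub_seed(seed, 601),
        )
        config = StackConfig(
            algorithms=("KNN", "PLS"), families=("B1", "B2"), k=5,
            base_folds=3, selection_folds=3, seed=_sub_seed(seed, 602),
        )
        model, _ = fit_stack(blocks, y, config)
        return evaluate(ty, model.predict_from_blocks(tb)).to_json()

    a, b = one_run(), one_run()
    return {"determinism_identical_runs": int(a == b)}


def end_to_end_smiles_benchmark(seed: int = 0) -> dict:
    """Full SMILES pipeline on a synthetic dataset: generate, split,
    train the scaled stack on two fingerprint families, evaluate, and
    audit the chemical space of the split."""
    from .chemspace import scaffold_uniqueness, tanimoto_audit
    from .curation import SplitSpec, split_train_test
    from .featurize import compute_descriptor_block
    from .stack import predict as stack_predict
    from .synthetic import SyntheticSpec, generate_smiles_dataset

    ds = generate_smiles_dataset(
        SyntheticSpec(n_active=300, n_inactive=60, seed=_sub_seed(seed, 700))
    )
    train, test = split_train_test(
        ds, SplitSpec(train_fraction=0.75, seed=_sub_seed(seed, 701))
    )
    families = ("FP4C", "MACCS")
    blocks = {
        fam: compute_descriptor_block(train.smiles, fam).matrix
        for fam in families
    }
    config = StackConfig(
        algorithms=ENSEMBLE_ALGORITHMS, families=families, k=5,
        base_folds=5, selection_folds=5, seed=_sub_seed(seed, 702),
    )
    model, _ = fit_stack(blocks, train.labels, config)
    table = stack_predict(model, test.smiles)
    report = evaluate(test.labels, table["probability"].to_numpy())
    scaf = scaffold_uniqueness(train.smiles, test.smiles)
    mean_sim, below, _ = tanimoto_audit(train.smiles, test.smiles)
    return {
        "e2e_test_mcc": report.mcc,
        "e2e_test_bacc": report.bacc,
        "e2e_test_auc": report.auc,
        "e2e_chosen_m": model.selection.chosen_m,
        "e2e_scaffold_unique_fraction": scaf,
        "e2e_tanimoto_mean": mean_sim,
        "e2e_tanimoto_below_half_fraction": below,
        "n_train": len(train.records),
        "n_test": len(test.records),
    }
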