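"""chemstack: stacked-ensemble QSAR bioactivity classification under
class imbalance.

Pipeline: activity-table curation → SMILES descriptor blocks → disjoint
balanced under-sampling → base-classifier probability features → MDGI
feature selection → SVM meta-classifier → evaluation, chemical-space
audit, and virtual screening.
"""

__version__ = "0.1.0"

from .curation import (
    CompoundRecord,
    CuratedDataset,
    SplitSpec,
    curate_dataset,
    label_activity,
    parse_activity_table,
    split_train_test,
    to_pic50,
)
from .featurize import (
    DescriptorBlock,
    FAMILY_REGISTRY,
    PhyschemProfile,
    ScaffoldKey,
    compute_descriptor_block,
    compute_physchem,
    ecfp4,
    murcko_scaffold,
    standardize_structure,
    tanimoto,
)
from .metrics import (
    ConfusionCounts,
    MetricsReport,
    auc_score,
    compute_metrics,
    confusion,
    cross_validate,
    evaluate,
)
from .sampling import BalancedSubset, make_balanced_subsets, subset_coverage_report
from .stack import (
    BaseModelKey,
    MetaModel,
    PFVMatrix,
    SelectionResult,
    StackConfig,
    build_pfv,
    fit_meta,
    fit_stack,
    oof_probability,
    predict,
    rank_pfs_mdgi,
    screen_library,
    select_feature_subset,
    train_base_matrix,
    tune_base_classifier,
)
from .synthetic import (
    SyntheticSpec,
    generate_block_dataset,
    generate_feature_dataset,
    generate_smiles_dataset,
)

__all__ = [name for name in dir() if not name.startswith("_")]
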