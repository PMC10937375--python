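"""pdskit: pathway-level tumor subtyping toolkit.

Single-sample gene-set scoring (ssGSEA / GSVA), unsupervised pathway-level
class discovery, subtype-specific feature selection, a probability-
thresholded RBF-SVM classifier with "mixed" calls, derived stem /
proliferation / replication-stress indices, and a ground-truth synthetic
cohort generator.
"""

from .formats_io import (
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    collapse_features,
    filter_low_variance,
    filter_sets,
    read_expression,
    read_gmt,
    write_expression,
    write_gmt,
)
from .enrichment import (
    EnrichmentParams,
    ScoreMatrix,
    gsva_scores,
    rank_transform,
    score_with_stored_range,
    ssgsea_scores,
)
from .discovery import (
    DiscoveryConfig,
    DiscoveryResult,
    discover,
    embed_scores,
    kmeans_cluster,
    select_k,
)
from .feature_selection import (
    FeatureSelectionConfig,
    prune_correlated,
    select_features,
    subtype_specific_sets,
)
from .classifier import (
    BatchModel,
    ClassifierModel,
    SubtypeCall,
    TrainConfig,
    calls_from_probabilities,
    combat_reference,
    mixed_fraction,
    predict,
    split_train_test,
    train_classifier,
    tune_svm_loocv,
)
from .indices import (
    proliferative_index,
    replication_stress,
    smi,
    stem_scores,
    tertile_high_labels,
)
from .synthetic_data import (
    SimulationTruth,
    simulate_cohort,
    simulate_differentiation_axis,
)

__version__ = "0.1.0"

__all__ = [
    "DataError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "ScoreMatrix",
    "EnrichmentParams",
    "DiscoveryConfig",
    "DiscoveryResult",
    "FeatureSelectionConfig",
    "BatchModel",
    "ClassifierModel",
    "SubtypeCall",
    "TrainConfig",
    "SimulationTruth",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "collapse_features",
    "filter_sets",
    "filter_low_variance",
    "rank_transform",
    "ssgsea_scores",
    "gsva_scores",
    "score_with_stored_range",
    "embed_scores",
    "kmeans_cluster",
    "select_k",
    "discover",
    "subtype_specific_sets",
    "prune_correlated",
    "select_features",
    "split_train_test",
    "combat_reference",
    "tune_svm_loocv",
    "train_classifier",
    "predict",
    "mixed_fraction",
    "smi",
    "proliferative_index",
    "replication_stress",
    "stem_scores",
    "tertile_high_labels",
    "simulate_cohort",
    "simulate_differentiation_axis",
]
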