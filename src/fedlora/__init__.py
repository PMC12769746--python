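"""fedlora: personalized, communication-efficient federated learning with
low-rank adapters on frozen EfficientNet backbones.

The package simulates a cross-silo federation for leukemia blood-smear
classification: a frozen EfficientNet-B0/B2 feature extractor shared by
all clients, trainable LoRA adapters as the only communicated payload,
a private classifier head per client, FedAdam server aggregation, and
exact parameter/communication accounting. A procedural smear-image
generator makes every stage testable without external data.
"""

from .backbone import (Backbone, LayerInventoryEntry, MBConvBlockSpec,
                       ScalingSpec, accounting_report, build_backbone,
                       compound_scale, count_parameters, layer_inventory,
                       load_checkpoint, save_checkpoint, stage_plan)
from .client import (Adam, ClientState, FocalLossParams, TrainLog,
                     centralized_train, compute_sampling_weights,
                     evaluate_client, focal_loss, focal_loss_and_grad,
                     local_train, personalized_forward, softmax)
from .lora import (AdapterState, DeltaUpdate, IncompatibleStateError,
                   LoRAAdapter, LoRAConfig, adapter_parameters, apply_delta,
                   default_target_rule, extract_delta, get_adapter_state,
                   inject_lora, load_delta, merge_adapters, payload_megabytes,
                   save_delta, set_adapter_state)
from .metrics import (ConfusionMatrix, CurvePoints, MetricsReport,
                      classification_metrics, cohens_kappa, confusion_matrix,
                      mcc, mcc_binary, micro_curves)
from .partition import (PartitionInfeasibleError, PartitionPlan, SplitSpec,
                        StratificationError, dirichlet_partition,
                        distribution_table, stratified_split)
from .server import (NOT_CONVERGED, FederationConfig, FederationResult,
                     ServerState, aggregate_deltas,
                     communication_cost_per_round, fedadam_step,
                     rounds_to_convergence, run_federation)
from .synthetic import (ClassMorphology, SmearDatasetSpec, apply_stain_shift,
                        client_stain_shifts, default_morphologies,
                        generate_dataset, generate_image,
                        normalization_stats, read_imagefolder,
                        to_model_input, write_imagefolder)

__version__ = "0.1.0"


def smoke_config(seed: int = 0) -> "FederationConfig":
    """Desk-scale federation configuration: the reduced ``s0`` backbone at
    96 px, rank-4 adapters, 10 clients, 5 rounds, and a client learning
    rate suited to randomly initialized (non-pretrained) features. Used by
    the test suite and the acceptance script."""
    return FederationConfig(
        variant="s0",
        rounds=5,
        client_lr=1e-2,
        client_val_fraction=0.2,
        lora=LoRAConfig(rank=4, alpha=8.0, dropout=0.1),
        seed=seed,
    )


def smoke_dataset_spec(seed: int = 0, images_per_class: int = 200,
                       resolution: int = 96) -> "SmearDatasetSpec":
    """The matching synthetic dataset: 4 x 200 images at 96 px."""
    return SmearDatasetSpec(
        images_per_class=(images_per_class,) * 4,
        resolution=resolution,
        seed=seed,
    )
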