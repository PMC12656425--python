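"""Shared fixtures: desk-scale configs and reusable synthetic cohorts."""

import numpy as np
import pytest

from voxfuse.contrastive import EncoderConfig
from voxfuse.fusion import ClassifierConfig
from voxfuse.synth import ClassProfile, CohortSpec, generate_cohort
from voxfuse.training import LabeledDataset


@pytest.fixture(scope="session")
def tiny_encoder_cfg() -> EncoderConfig:
    """Desk-scale encoder: d = 32, two conv layers, one attention layer."""
    return EncoderConfig(
        hidden_dim=32, conv_widths=(10, 8), conv_strides=(5, 4),
        attention_layers=1, heads=2, ffn_dim=32, projection_dim=16,
    )


@pytest.fixture(scope="session")
def small_clf_cfg() -> ClassifierConfig:
    """Desk-scale classifier for 22 biomarkers + 16 synthetic embeddings."""
    return ClassifierConfig(
        input_dim=38, hidden_dim=64, attn_tokens=4, attn_heads=2,
        ffn_dim=32, head_hidden=16,
    )


@pytest.fixture(scope="session")
def separable_dataset() -> LabeledDataset:
    """Strongly separated two-class cohort (default class profiles)."""
    cohort = generate_cohort(
        CohortSpec(n_subjects=40, samples_per_subject=5, seed=11)
    )
    return LabeledDataset.from_cohort(cohort)


@pytest.fixture(scope="session")
def null_dataset() -> LabeledDataset:
    """Identical class profiles and zero embedding separation: no signal."""
    profile = ClassProfile(jitter_rel=0.01, shimmer_rel=0.03, hnr_db=18.0)
    cohort = generate_cohort(
        CohortSpec(
            n_subjects=60, samples_per_subject=5, seed=12,
            profiles={0: profile, 1: profile}, embedding_separation=0.0,
        )
    )
    return LabeledDataset.from_cohort(cohort)
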