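"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from ctibench import synthetic
from ctibench.features_compound import encode_2dfp
from ctibench.features_target import encode_physchem, fit_physchem_pca
from ctibench.io_data import InteractionRecord, Measure, Source, Variant


def make_record(
    compound_id="C0",
    smiles="CCO",
    target_id="T0",
    sequence="ACDEFGHIKL",
    affinity=1.0,
    measure=Measure.KD_MICROMOLAR,
    label=1,
    variant=Variant.UNKNOWN,
) -> InteractionRecord:
    return InteractionRecord(
        compound_id=compound_id,
        smiles=smiles,
        target_id=target_id,
        sequence=sequence,
        affinity_value=affinity,
        measure=measure,
        label=label,
        source=Source.SYNTHETIC,
        variant=variant,
    )


@pytest.fixture(scope="session")
def property_table():
    return synthetic.synthetic_property_table(seed=0)


@pytest.fixture(scope="session")
def projection(property_table):
    return fit_physchem_pca(property_table)


@pytest.fixture(scope="session")
def small_dataset():
    """~200-pair planted-signal dataset used across splitter/eval tests."""
    spec = synthetic.SyntheticSpec(
        n_compounds=40, n_targets=12, n_pairs=200, prevalence=0.4, seed=11
    )
    compounds = synthetic.gen_compounds(spec.n_compounds, seed=11)
    targets = synthetic.gen_targets(spec.n_targets, seed=11)
    records = synthetic.gen_interactions(compounds, targets, spec)
    return compounds, targets, records


@pytest.fixture(scope="session")
def featurized_dataset(small_dataset, projection):
    """2D fingerprints + pooled physicochemical target vectors + labels."""
    _, _, records = small_dataset
    fps = {}
    tvecs = {}
    for r in records:
        if r.compound_id not in fps:
            fps[r.compound_id] = encode_2dfp(r.smiles).vector
        if r.target_id not in tvecs:
            m = encode_physchem(r.sequence, projection)
            body = m.matrix[: m.true_length]
            tvecs[r.target_id] = np.concatenate([body.mean(axis=0), body.max(axis=0)])
    xc = np.stack([fps[r.compound_id] for r in records]).astype(np.float32)
    xt = np.stack([tvecs[r.target_id] for r in records]).astype(np.float32)
    y = np.array([r.label for r in records], dtype=np.int64)
    return xc, xt, y
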