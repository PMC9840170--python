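import numpy as np
import pytest

from pathattn import (
    GeneVocabulary,
    ModelConfig,
    TrainingConfig,
    align_to_vocabulary,
    build_mask,
    generate,
    prepare_model_input,
    train,
)
from pathattn.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def toy_gmt(tmp_path_factory):
    """S1:{A,B}, S2:{B,C}, S3:{C} in GMT format."""
    path = tmp_path_factory.mktemp("gmt") / "toy.gmt"
    path.write_text("S1\tdesc\tA\tB\nS2\tdesc\tB\tC\nS3\tdesc\tC\n")
    return path


@pytest.fixture(scope="session")
def abc_vocab():
    return GeneVocabulary(("A", "B", "C"))


@pytest.fixture(scope="session")
def small_sim():
    """Tiny pathway-driven dataset for fast unit tests."""
    spec = SyntheticSpec(
        n_genes=60, n_ref_cells=300, n_query_cells=120, n_types=3,
        n_pathways=5, genes_per_pathway=8, effect=4.0, seed=5,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_model(small_sim):
    """A quickly trained small model plus its prepared reference and query."""
    ds = small_sim
    mask = build_mask(ds.truth_gmt, ds.reference.gene_names)
    ref = prepare_model_input(ds.reference)
    query = align_to_vocabulary(prepare_model_input(ds.query), ref.gene_names)
    mconfig = ModelConfig(m=16, heads=2, seed=5)
    tconfig = TrainingConfig(epochs=12, batch_size=32, seed=5)
    state, history = train(ref, mask, mconfig, tconfig)
    return dict(ds=ds, mask=mask, ref=ref, query=query, state=state,
                history=history, mconfig=mconfig, tconfig=tconfig)


# ---- full-size study fixtures shared by the acceptance tests --------------

@pytest.fixture(scope="session")
def default_run():
    """Default synthetic study: 5 types, disjoint drivers, 2000+1000 cells."""
    ds = generate(SyntheticSpec(seed=1))
    mask = build_mask(ds.truth_gmt, ds.reference.gene_names)
    ref = prepare_model_input(ds.reference)
    query = align_to_vocabulary(prepare_model_input(ds.query), ref.gene_names)
    state, history = train(ref, mask, ModelConfig(seed=1), TrainingConfig(seed=1))
    return dict(ds=ds, mask=mask, ref=ref, query=query, state=state, history=history)


@pytest.fixture(scope="session")
def holdout_run():
    """Same study with one cell type absent from the reference."""
    ds = generate(SyntheticSpec(seed=1, holdout_type="T4"))
    mask = build_mask(ds.truth_gmt, ds.reference.gene_names)
    ref = prepare_model_input(ds.reference)
    query = align_to_vocabulary(prepare_model_input(ds.query), ref.gene_names)
    state, history = train(ref, mask, ModelConfig(seed=1), TrainingConfig(seed=1))
    return dict(ds=ds, mask=mask, ref=ref, query=query, state=state, history=history)
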