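from types import SimpleNamespace

import numpy as np
import pytest

import erosionscan as es


@pytest.fixture(scope="session")
def ref_proteome():
    rng = np.random.default_rng(1)
    return es.random_proteome(140, rng)


@pytest.fixture(scope="session")
def synth_bundle(ref_proteome):
    """Default synthetic eroding genome: 100 genes, 31.2% pseudogenized,
    12 IS insertions in 3 families, chromosome + two plasmids."""
    cfg = es.SynthConfig(seed=7)
    genome, features, truth = es.generate_genome(cfg, ref_proteome)
    return SimpleNamespace(cfg=cfg, genome=genome, features=features,
                           truth=truth, proteome=ref_proteome)


@pytest.fixture(scope="session")
def called_bundle(synth_bundle):
    called, calls = es.call_pseudogenes(
        synth_bundle.genome, synth_bundle.features, synth_bundle.proteome)
    return SimpleNamespace(called=called, calls=calls, **vars(synth_bundle))


@pytest.fixture(scope="session")
def is_bundle(synth_bundle):
    cfg = es.ISConfig()
    families = es.find_repeat_families(synth_bundle.genome, cfg)
    hits = es.scan_homology(synth_bundle.genome,
                            dict(synth_bundle.truth.is_families), cfg)
    remnants = es.merge_fragments(hits, families, cfg)
    n_orfs, n_long, table = es.census_transposase_orfs(
        synth_bundle.genome, remnants, cfg, families)
    ns = SimpleNamespace(**vars(synth_bundle))
    ns.cfg = cfg
    ns.families = families
    ns.hits = hits
    ns.remnants = remnants
    ns.n_orfs = n_orfs
    ns.n_long = n_long
    ns.orf_table = table
    return ns


def event_of(feature_id: str) -> str:
    """Planted split pseudogenes annotate as two features <event>a/<event>b."""
    return feature_id[:-1] if feature_id[-1] in "ab" else feature_id
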