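import numpy as np
import pytest

import mitochip as mc


@pytest.fixture(scope="session")
def chrm_ref():
    return mc.make_chrm_reference(1)


@pytest.fixture(scope="session")
def chrm(chrm_ref):
    return chrm_ref[0]


@pytest.fixture(scope="session")
def annotation(chrm_ref):
    return chrm_ref[1]


@pytest.fixture(scope="session")
def bundle(chrm_ref):
    """chrM plus a 300-kb decoy with 2 NUMTs (5% divergence) and repeats."""
    chrm, ann = chrm_ref
    decoy = mc.make_nuclear_decoy(
        2, chrm, total_size=300_000, n_numts=2, numt_lengths=[500, 800],
        divergence=0.05,
    )
    return mc.ReferenceBundle(chrm, ann, decoy)


@pytest.fixture(scope="session")
def chrm_only_bundle(chrm_ref):
    chrm, ann = chrm_ref
    return mc.ReferenceBundle(chrm, ann, None)


@pytest.fixture(scope="session")
def chrm_index(chrm):
    return mc.ExactMatchIndex([(chrm.name, chrm.codes)], k=36,
                              circular={chrm.name})


@pytest.fixture(scope="session")
def genome_index(bundle):
    return mc.ExactMatchIndex(bundle.contig_codes(), k=36,
                              circular={bundle.chrm.name})


def chrm_coverage(reads, chrm, chrm_index, seed=0):
    """Map reads to chrM and build the circular end-density track."""
    aln = mc.map_reads(reads, chrm_index, rng=np.random.default_rng(seed))
    aln = aln[aln["status"] != "unmapped"]
    return mc.build_coverage(aln, chrm.name, chrm.length, circular=True)


@pytest.fixture(scope="session")
def make_chrm_coverage(chrm, chrm_index):
    def _make(model, seed, n=100_000, bias=None, **kw):
        ann = mc.genome.default_annotation(chrm.name, chrm.length)
        bundle = mc.ReferenceBundle(chrm, ann, None)
        frac = {"mito_mass_fraction": 1.0} if model == "input" else \
               {"chip_mito_fraction": 1.0}
        cfg = mc.SimConfig(seed=seed, n_fragments=n,
                           bias_field={chrm.name: bias} if bias is not None
                           else None, **frac, **kw)
        lib = mc.simulate_library(cfg, model, bundle)
        return chrm_coverage(lib.reads, chrm, chrm_index, seed=seed), lib
    return _make
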