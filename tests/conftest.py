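import numpy as np
import pytest

import literank as lr

MEDLINE_FIXTURE = """\
PMID- 10000001
DP  - 2003 Jun
TI  - Stroke risk and blood pressure in a cohort study.
AB  - We examined stroke incidence in relation to blood pressure.
      Elevated pressure was associated with increased risk of
      ischemic events. The association persisted after adjustment
      for age and smoking status.

PMID- 10000002
DP  - 2010
TI  - Cortisol levels and mood disorders.

PMID- 10000003
AB  - Vitamin E supplementation showed no protective effect.

"""


@pytest.fixture
def medline_text():
    return MEDLINE_FIXTURE


@pytest.fixture
def small_config():
    """Planted corpus small enough for per-test matrix decompositions."""
    return lr.PlantedCorpusConfig(
        n_topics=3,
        words_per_topic=8,
        n_factors=6,
        docs_per_factor=12,
        doc_length=25,
        background_noise=0.2,
        n_background_words=20,
        seed=11,
    )


@pytest.fixture
def small_space(small_config):
    """Dictionary + collection + eigen space built from the planted corpus."""
    collection, truth = lr.generate_planted_corpus(small_config)
    headings = lr.generate_mesh_fixture(30, seed=small_config.seed, config=small_config)
    dictionary = lr.filter_vocabulary(lr.build_vocabulary(headings))
    matrix = lr.build_matrix(collection, dictionary, weighting="log-entropy")
    space = lr.decompose(matrix)
    return collection, truth, dictionary, matrix, space


@pytest.fixture
def reference_params():
    """Well-separated tri-modal mixture used across recovery tests."""
    return lr.TriModalParams(
        alpha=(5.0, 10.0, 5.0), mu=(-0.4, 0.05, 0.45), sigma=(0.1, 0.12, 0.1)
    )


def exact_histogram(params, n_bins=40):
    """Noiseless (bin center, height) evaluations of the tri-modal curve."""
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, lr.trimodal_density(centers, params)
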