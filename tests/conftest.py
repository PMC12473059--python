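import pytest

import psorimetrics as pm

WOS_PLAIN_FIXTURE = """\
FN Clarivate Analytics Web of Science
VR 1.0
PT J
AU Smith, A
   Jones, B
TI Secukinumab in moderate plaque psoriasis
SO British Journal of Dermatology
LA English
DT Article
DE Psoriasis; Secukinumab
ID IL-17; SAFETY
C1 Univ Oradea, Oradea, Romania
TC 12
PY 2014
DI 10.1111/test.1
UT WOS:000001
ER

PT J
AU Doe, C
TI Methotrexate dosing revisited
SO Journal of Rheumatology
LA English
DT Review
DE Methotrexate; Psoriatic Arthritis
C1 Cardiff Univ, Wales
PY 1998
UT WOS:000002
ER

PT J
AU Lee, D
TI TNF-alpha blockade in rheumatoid arthritis
SO Lancet
LA German
DT Letter
DE TNF-alpha
C1 Harvard Univ, Boston, MA 02115 USA
TC 3
PY 2005
DI 10.1111/test.3
UT WOS:000003
ER

EF
"""


@pytest.fixture(scope="session")
def wos_plain_text():
    return WOS_PLAIN_FIXTURE


@pytest.fixture(scope="session")
def corpus_and_truth():
    """Default synthetic corpus (fixed seed 0): the study conditions."""
    return pm.generate_corpus(pm.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def normalized(corpus_and_truth):
    records, _ = corpus_and_truth
    return pm.normalize_corpus(records)


@pytest.fixture(scope="session")
def small_synthetic_config():
    """Reduced schedule for tests that regenerate corpora repeatedly."""
    return pm.SyntheticConfig(
        seed=3,
        phase_schedule=[(1975, 1990, 1), (1991, 2004, 3), (2005, 2015, 8), (2016, 2025, 15)],
    )
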