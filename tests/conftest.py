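import pytest
from hypothesis import HealthCheck, settings

from mtscape.catalog import Catalog, PresequenceRecord
from mtscape.landscape import ClusterModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_model_from_truth(truth: dict[str, str]) -> ClusterModel:
    """Build a ClusterModel whose partition is exactly the ground truth.

    Used where the clustering itself is not under test (group statistics,
    permutation machinery).
    """
    return ClusterModel.from_assignments(truth)


@pytest.fixture
def toy_catalog() -> Catalog:
    return Catalog(
        [
            PresequenceRecord("ATP5", "MLSRAVCGTSRQLAPVLGYLG", 0.95, 5, "test"),
            PresequenceRecord("COX4", "MLSLRQSIRFFKPATRTLCSSR", 0.88, 3, "test"),
            PresequenceRecord("OXA1", "MFKLTSRLALSSRSILVRSIPVRFY", 0.71, 1, "test"),
        ]
    )


@pytest.fixture(scope="session")
def curation_fixture_rows():
    """20 records whose curated outcome is known by hand.

    Hand count for curate() = filter → dedup → drop_trivial:
    filter drops 4 records lacking a score (GENE_L/N/O and the
    scoreless GENE_D duplicate), 3 with score < 0.3 (GENE_I/J/K), and
    2 below the length floor (GENE_H at 7 residues and the Met-only
    GENE_M).  Deduplication collapses GENE_A (times 5 wins), GENE_B
    (tied times, length 31 wins) and GENE_C (times 4 wins), removing 4
    more.  Nothing is left for drop_trivial.  Final catalog: 7 records
    A–G.
    """
    mk = PresequenceRecord
    return [
        # GENE_A: three forms; times 5 wins
        mk("GENE_A", "MLRSSRAVGT", 0.90, 5),
        mk("GENE_A", "MLRSSRAVGTAA", 0.90, 2),
        mk("GENE_A", "MLRSSR" + "A" * 10, 0.90, 1),
        # GENE_B: tied times, longer (31) wins
        mk("GENE_B", "M" + "L" * 19, 0.80, 3),
        mk("GENE_B", "M" + "L" * 30, 0.80, 3),
        # clean keepers
        mk("GENE_C", "MKRLLSTAVR", 0.30, 4),     # boundary score retained
        mk("GENE_D", "MSTRLLKAVRGG", 0.55, 2),
        mk("GENE_E", "MFSTKRAV", 0.45, 1),       # boundary length 8 retained
        mk("GENE_F", "MLLKRSSTAVGQ", 0.99, 7),
        mk("GENE_G", "MQNRKLSTAVLL", 0.62, 2),
        # dropped by score < 0.3
        mk("GENE_I", "MLRSSRAVGT", 0.29, 5),
        mk("GENE_J", "MKKLLSTAVR", 0.10, 5),
        mk("GENE_K", "MSSTRLLKAV", 0.05, 2),
        # dropped: no score
        mk("GENE_L", "MLRSSRAVGT", None, 5),
        mk("GENE_N", "MKRLLSTAVR", None, 1),
        mk("GENE_O", "MSSTRLLKAV", None, 2),
        # dropped by length (7 < 8) despite high score
        mk("GENE_H", "MFSTKRA", 0.95, 9),
        # length-1 Met-only presequence, survives filter, dropped as trivial
        mk("GENE_M", "M", 0.80, 2),
        # another duplicate pair for GENE_C: lower times loses
        mk("GENE_C", "MKRLLSTAVRXX".replace("X", "A"), 0.30, 1),
        # scoreless duplicate of GENE_D also dropped by score filter
        mk("GENE_D", "MSTRLLKAVRGGAA", None, 9),
    ]
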