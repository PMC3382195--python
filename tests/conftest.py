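import numpy as np
import pytest

from pbscope.pb_core import PB_LABELS, default_prototype_table
from pbscope.substitution import DomainPairAlignment, SubstitutionMatrix


@pytest.fixture(scope="session")
def table():
    return default_prototype_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_pair(
    pb1,
    pb2,
    distances=None,
    columns=None,
    family="famA",
    scop_class="all-alpha",
    identity=20.0,
    aa1=None,
    aa2=None,
    **kw,
):
    """Hand-built DomainPairAlignment for fixtures (gapless by default)."""
    if columns is None:
        assert len(pb1) == len(pb2)
        columns = [(i, i) for i in range(len(pb1))]
    if distances is None:
        distances = [0.0 if (i >= 0 and j >= 0) else np.nan for i, j in columns]
    n1 = max(i for i, _ in columns) + 1
    n2 = max(j for _, j in columns) + 1
    return DomainPairAlignment(
        id1=f"{family}_x",
        id2=f"{family}_y",
        family=family,
        scop_class=scop_class,
        columns=columns,
        distances=np.asarray(distances, float),
        aa1=aa1 or "A" * n1,
        aa2=aa2 or "A" * n2,
        pb1=pb1,
        pb2=pb2,
        identity=identity,
        **kw,
    )


def toy_matrix(match=2.0, mismatch=-1.0):
    """Uniform match/mismatch scores over the full PB alphabet."""
    scores = np.full((16, 16), mismatch)
    np.fill_diagonal(scores, match)
    return SubstitutionMatrix(labels=list(PB_LABELS), scores=scores, id="toy")
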