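import numpy as np
import pytest

from fieldstore import SensorStore


@pytest.fixture
def field_store():
    """A small field trial: 4 irrigated + 4 rainfed plots, 2 streams each."""
    st = SensorStore()
    st.create_entity("user", "csiro-hb", attrs={"description": "phenomics group"})
    st.create_entity("experiment", "yanco-2013", "csiro-hb")
    st.tree.set_metadata("csiro-hb~yanco-2013", "sowing-date", "2013-05-21")
    for i in range(8):
        treatment = "irrigated" if i < 4 else "rainfed"
        node = f"plot-R{i // 4 + 1}C{i % 4 + 1}"
        st.create_entity(
            "node", node, "csiro-hb~yanco-2013", attrs={"latitude": -34.6, "longitude": 146.4}
        )
        st.tree.set_metadata(f"csiro-hb~yanco-2013~{node}", "treatment", treatment)
        st.create_entity(
            "stream", "canopy-temp", f"csiro-hb~yanco-2013~{node}", attrs={"unit": "degC"}
        )
        st.create_entity(
            "stream",
            "soil-moisture-30cm",
            f"csiro-hb~yanco-2013~{node}",
            attrs={"unit": "%vol"},
        )
    return st


@pytest.fixture
def one_stream_store():
    """A store with a single empty stream at u~e~n~s."""
    st = SensorStore()
    st.create_entity("user", "u")
    st.create_entity("experiment", "e", "u")
    st.create_entity("node", "n", "u~e")
    st.create_entity("stream", "s", "u~e~n", attrs={"unit": "degC"})
    return st


def random_points(rng: np.random.Generator, n: int, t_max: int = 63_072_000):
    """n duplicate-free (timestamp, value) pairs in arbitrary arrival order."""
    ts = rng.choice(t_max, size=n, replace=False).astype(np.int64)
    vs = rng.normal(15.0, 8.0, n)
    return np.column_stack([ts, vs])
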