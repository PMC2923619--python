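import pytest

from phylodraw import Canvas, FixtureParams, generate_tree


@pytest.fixture
def canvas():
    """440x300 canvas whose branch area is exactly 300 px wide."""
    return Canvas(width=440.0, height=300.0, margin=10.0, label_gutter=120.0)


@pytest.fixture
def chart_canvas():
    """Canvas with a 60 px chart gutter for track tests."""
    return Canvas(width=600.0, height=600.0, margin=10.0, label_gutter=100.0,
                  chart_gutter=60.0)


def make_tree(n_leaves, seed, **kw):
    return generate_tree(FixtureParams(n_leaves=n_leaves, seed=seed, **kw))


@pytest.fixture
def fixture_trees():
    """A spread of seeded random trees, 1..60 leaves."""
    return [make_tree(n, seed) for seed, n in enumerate([1, 2, 3, 5, 8, 13, 21, 34, 60])]
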