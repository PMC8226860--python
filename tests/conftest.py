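import numpy as np
import pandas as pd
import pytest

from standrecover import AbundanceTable, FeatureKind, Rank, StudyMetadata


def make_table(values, feature_kind=FeatureKind.taxon, rank=Rank.species,
               is_relative=False, sample_ids=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return AbundanceTable(
        sample_ids=tuple(sample_ids or (f"s{i+1}" for i in range(n))),
        feature_ids=tuple(feature_ids or (f"f{j+1}" for j in range(m))),
        values=values,
        feature_kind=feature_kind,
        rank=rank if FeatureKind(feature_kind) is FeatureKind.taxon else None,
        is_relative=is_relative,
    )


def make_metadata(stands, env=None, sample_ids=None):
    """Metadata from a list of per-sample stand labels."""
    n = len(stands)
    sample_ids = tuple(sample_ids or (f"s{i+1}" for i in range(n)))
    env = pd.DataFrame(env if env is not None else {"pH": np.linspace(4, 6, n)},
                       index=list(sample_ids))
    plot_counter: dict[str, int] = {}
    plots = []
    for s in stands:
        plot_counter[s] = plot_counter.get(s, 0) + 1
        plots.append(f"p{plot_counter[s]}")
    return StudyMetadata(sample_ids=sample_ids, stand=tuple(stands),
                         plot=tuple(plots), env=env)


@pytest.fixture
def nine_sample_meta():
    return make_metadata(["25-year-old"] * 3 + ["40-year-old"] * 3 + ["PCF"] * 3)
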