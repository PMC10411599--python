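import numpy as np
import pandas as pd
import pytest

from cagecall.clustering import PooledSignal, pool_and_normalize
from cagecall.ctss_io import CtssTrack
from cagecall.simulate import SimConfig, generate_dataset


def make_track(entries, sample_id="s1", library_size=1_000_000):
    """Build a CtssTrack from (chrom, pos, strand, count) tuples."""
    data = pd.DataFrame(entries, columns=["chrom", "pos", "strand", "count"])
    return CtssTrack(sample_id=sample_id, library_size=library_size, data=data)


def make_pooled(entries, library_size=1_000_000):
    """PooledSignal from a single synthetic track."""
    return pool_and_normalize([make_track(entries, library_size=library_size)])


@pytest.fixture(scope="session")
def default_sim():
    """The default desk-scale synthetic data set (fixed seed for the suite)."""
    return generate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def called_clusters(default_sim):
    """Pooled signal plus called/quantified clusters for the default data set."""
    import cagecall as cc

    sim = default_sim
    pooled = cc.pool_and_normalize(sim.tracks)
    tss = cc.cluster_unidirectional(pooled)
    enh = cc.cluster_bidirectional(pooled)
    tss_m = cc.quantify(tss, sim.tracks)
    enh_m = cc.quantify(enh, sim.tracks)
    return {"pooled": pooled, "tss": tss_m, "enh": enh_m}
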