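import numpy as np
import pytest

from panelkit import qc
from panelkit import simulate as sm
from panelkit.calls import GenotypeMatrix


@pytest.fixture(scope="session")
def study():
    """Default desk-scale study: 3 populations + admixture, artifacts,
    clones, one sport, three Mendelian traits."""
    return sm.simulate_study(sm.SimConfig(seed=101))


@pytest.fixture(scope="session")
def analysis(study):
    """QC'd panel restricted to the analysis marker set (HWE filter off:
    the panel is heavily selfing, as the germplasm it emulates)."""
    panel, info, phen, truth = study
    fpanel, res = qc.run_qc(panel, info, hwe_alpha=0.0)
    apanel = fpanel.subset(markers=res.analysis_markers)
    return apanel, phen, truth


def make_panel(calls, sample_ids=None, marker_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    marker_ids = marker_ids or [f"m{j}" for j in range(m)]
    return GenotypeMatrix(sample_ids, marker_ids, calls)
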