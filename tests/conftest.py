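import numpy as np
import pytest
from hypothesis import settings

from lairkit.genome import lair_index
from lairkit.segmentation import call_sample
from lairkit.simulate import (
    ScenarioProfile,
    SignalModel,
    make_marker_panel,
    simulate_array,
    simulate_karyotype,
    simulate_reference,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


NOISELESS = SignalModel(f=1.0, sigma_r=0.0, sigma_l=0.0, scale_sd=0.0, nc_rate=0.0, crosstalk=0.0, seed=0)


@pytest.fixture(scope="session")
def default_model():
    return SignalModel(seed=0)


@pytest.fixture(scope="session")
def noiseless_model():
    return NOISELESS


@pytest.fixture(scope="session")
def near_haploid_callset():
    """A near-haploid tumour simulated and called end to end (shared)."""
    model = SignalModel(f=1.0, seed=21)
    karyo = simulate_karyotype(ScenarioProfile("near_haploid_chr7AB"))
    panel = make_marker_panel(model, seed=22)
    arr, truth = simulate_array(karyo, model, panel=panel, seed=23)
    refs = [simulate_reference(panel, model, seed=s) for s in (24, 25)]
    true_di = lair_index(karyo)
    result = call_sample(arr, refs, flow_di=true_di, seed=1)
    return {
        "model": model,
        "karyotype": karyo,
        "panel": panel,
        "array": arr,
        "truth": truth,
        "references": refs,
        "true_di": true_di,
        "result": result,
    }


def state_match_fraction(karyotype, result, build):
    """Autosomal genome length fraction where called states equal the truth."""
    matched = total = 0.0
    for call in result.calls:
        seg = call.segment
        if seg.chrom == "chrX" or seg.chrom == "chrY":
            continue
        for true_seg, true_state in karyotype.segments:
            if true_seg.chrom != seg.chrom:
                continue
            lo = max(seg.start, true_seg.start)
            hi = min(seg.end, true_seg.end)
            if lo > hi:
                continue
            total += hi - lo + 1
            if call.state == true_state:
                matched += hi - lo + 1
    return matched / total


rng_seed = 0  # module-level convenience for tests needing a fixed generator


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
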