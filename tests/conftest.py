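import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adipomr.simulate import SyntheticConfig, generate_two_sample_dataset
from adipomr.sumstats import (
    HarmonizedInstrument,
    InstrumentSet,
    SummaryStatRecord,
    frame_to_records,
    harmonize,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def build_instruments(gamma, se_gamma, Gamma, se_Gamma, gamma2=None, se_gamma2=None, eaf=None):
    """Assemble an InstrumentSet directly from effect arrays."""
    n = len(gamma)
    gamma2 = [None] * n if gamma2 is None else gamma2
    se_gamma2 = [None] * n if se_gamma2 is None else se_gamma2
    eaf = [None] * n if eaf is None else eaf
    instruments = [
        HarmonizedInstrument(
            variant_id=f"rs{i + 1}",
            gamma=float(gamma[i]),
            se_gamma=float(se_gamma[i]),
            Gamma=float(Gamma[i]),
            se_Gamma=float(se_Gamma[i]),
            aligned_allele="A",
            gamma2=None if gamma2[i] is None else float(gamma2[i]),
            se_gamma2=None if se_gamma2[i] is None else float(se_gamma2[i]),
            eaf=None if eaf[i] is None else float(eaf[i]),
        )
        for i in range(n)
    ]
    return InstrumentSet(exposure_name="exposure", unit="kg/m^2", instruments=instruments)


def random_instruments(rng, n_snps=10, with_second=False):
    gamma = rng.normal(0.05, 0.02, n_snps)
    gamma[np.abs(gamma) < 1e-3] = 0.02
    kwargs = {}
    if with_second:
        kwargs["gamma2"] = rng.normal(0.04, 0.02, n_snps)
        kwargs["se_gamma2"] = rng.uniform(0.002, 0.01, n_snps)
    return build_instruments(
        gamma,
        rng.uniform(0.002, 0.01, n_snps),
        rng.normal(0.005, 0.01, n_snps),
        rng.uniform(0.005, 0.02, n_snps),
        **kwargs,
    )


def simulate_harmonized(config: SyntheticConfig) -> tuple[InstrumentSet, object]:
    """Simulate a two-sample dataset and harmonize it; returns (set, model)."""
    ds = generate_two_sample_dataset(config)
    second = None if ds.exposure2 is None else frame_to_records(ds.exposure2)
    inst = harmonize(
        frame_to_records(ds.exposure),
        frame_to_records(ds.outcome),
        second_exposure_records=second,
    )
    return inst, ds.model


def make_record(vid="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-9, n=1000.0,
                eaf=None, info=None, hwe_p=None):
    return SummaryStatRecord(
        variant_id=vid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pval=pval, n=n, eaf=eaf, info=info, hwe_p=hwe_p,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
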