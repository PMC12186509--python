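import pytest

from vwecon import study
from vwecon.accounting import PayerClass, per_case_rates


@pytest.fixture(scope="session")
def base_ledgers():
    """The five base-case payer-group ledgers."""
    return study.base_case_ledgers()


@pytest.fixture(scope="session")
def base_rates(base_ledgers):
    """Per-patient rate components for scenario work (Tricare/VA folded
    into the commercial head-count, which keeps its own rates)."""
    rates = {l.payer: per_case_rates(l) for l in base_ledgers}
    rates.pop(PayerClass.TRICARE_VA)
    return rates


@pytest.fixture(scope="session")
def ledger_by_payer(base_ledgers):
    return {l.payer: l for l in base_ledgers}
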