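from __future__ import annotations

import pytest

from alarmaudit.parsing import parse_records
from alarmaudit.samples import (load_sample_desat_limits,
                                load_sample_hr_priority_pair,
                                load_sample_unit_log)


@pytest.fixture(scope="session")
def unit_log_records():
    return load_sample_unit_log()


@pytest.fixture(scope="session")
def unit_log_parsed(unit_log_records):
    return parse_records(unit_log_records, strict=True)


@pytest.fixture(scope="session")
def desat_parsed():
    return parse_records(load_sample_desat_limits(), strict=True)


@pytest.fixture(scope="session")
def hr_pair_parsed():
    return parse_records(load_sample_hr_priority_pair(), strict=True)
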