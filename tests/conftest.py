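import numpy as np
import pytest

from mdisw import (
    PairCountTable,
    allocate_phase_order,
    assign_rows_B,
    assign_sequences_A,
    build_schedule_A,
    build_schedule_B,
    complete_latin_squares,
)

STANDARDS6 = ["Sa", "Sb", "Sc", "Sd", "Se", "Sf"]

# Worked example: 40 facilities choosing pairs of four standards, with the
# published frequency distribution of pair choices.
TABLE3_COUNTS = {
    ("Sa", "Sb"): 14,
    ("Sa", "Sc"): 8,
    ("Sa", "Sd"): 6,
    ("Sb", "Sc"): 4,
    ("Sb", "Sd"): 3,
    ("Sc", "Sd"): 5,
}


@pytest.fixture(scope="session")
def table3_pairs() -> PairCountTable:
    return PairCountTable(dict(TABLE3_COUNTS))


@pytest.fixture(scope="session")
def design_A_schedules(table3_pairs):
    allocation = allocate_phase_order(table3_pairs, seed=1)
    table = assign_sequences_A(table3_pairs, allocation, seed=1)
    return build_schedule_A(table)


@pytest.fixture(scope="session")
def design_B_assignment():
    squares = complete_latin_squares(STANDARDS6, 3, seed=1)
    return assign_rows_B(squares, [f"f{i:02d}" for i in range(18)], seed=1)


@pytest.fixture(scope="session")
def design_B_schedules(design_B_assignment):
    return build_schedule_B(design_B_assignment)


@pytest.fixture(scope="session")
def design_B_40_schedules():
    """A larger six-standard overlapping-cycle trial: 40 facilities."""
    squares = complete_latin_squares(STANDARDS6, 7, seed=7)
    rows = []
    i = 0
    for sq in squares:
        for row in sq.rows:
            if i < 40:
                rows.append((f"f{i:02d}", row, 1 + i % 2))
                i += 1
    return build_schedule_B(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
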