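import csv
import io
import itertools
from importlib.resources import files

import pytest

from semcds import staging


@pytest.fixture(scope="session")
def bcs7():
    return staging.bundled_ruleset("bcs7")


@pytest.fixture(scope="session")
def bcs8():
    return staging.bundled_ruleset("bcs8-subset")


@pytest.fixture(scope="session")
def bcs7_raw_rows():
    """The edition-7 fixture parsed independently of the rule engine."""
    text = files("semcds").joinpath("data", "bcs7_rules.csv").read_text("utf-8")
    rows = []
    in_rules = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cells = next(csv.reader(io.StringIO(line)))
        if cells[0] == "rule_id":
            in_rules = True
            continue
        if cells[0] == "stage":
            in_rules = False
            continue
        if in_rules:
            rows.append(cells)
    return rows


def naive_scan(rows, values):
    """Independent oracle: scan all rows, test all fields, return stages of
    matching rows.  ``rows`` are raw CSV cells; ``values`` maps field→value."""
    order = ("t", "n", "m", "grade", "her2", "er", "pr")
    hits = []
    for cells in rows:
        rule_id, _edition, *patterns, stage = cells
        ok = all(
            p == "*" or p == values.get(f)
            for f, p in zip(order, patterns)
        )
        if ok:
            hits.append((rule_id, stage))
    return hits


def tnm_grid():
    """The full 60-element T×N×M enumeration."""
    return [
        staging.TnmCategory(t, n, m)
        for t, n, m in itertools.product(
            staging.T_CATEGORIES, staging.N_CATEGORIES, staging.M_CATEGORIES
        )
    ]
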