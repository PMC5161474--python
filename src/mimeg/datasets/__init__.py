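"""Bundled worked-example tables.

Transcribed published accuracy tables used as fixtures for the aggregation
and rank-statistics worked examples:

* ``table1`` — online left-vs-right accuracies, one column, 17 sessions;
* ``table2`` — classifier comparison (CSP and STFT features), 4 classifiers;
* ``table3`` — left-vs-right 5-fold CV accuracies, 17 sessions x 10 methods;
* ``table4`` — imagery-vs-rest 5-fold CV accuracies, same layout;
* ``table7`` — inter-session accuracies, 16 sessions (two per subject)
  x 10 methods.

Cells are data only; summary rows/columns are always recomputed.
"""

from importlib import resources

from ..comparison import AccuracyTable

__all__ = ["load_table", "available_tables"]

_TABLES = ("table1", "table2", "table3", "table4", "table7")


def available_tables() -> tuple[str, ...]:
    return _TABLES


def load_table(name: str) -> AccuracyTable:
    """Load a bundled table by name (e.g. ``'table3'``)."""
    if name not in _TABLES:
        raise KeyError(f"unknown table {name!r}; available: {_TABLES}")
    ref = resources.files(__package__).joinpath(f"tables/{name}.tsv")
    with resources.as_file(ref) as path:
        return AccuracyTable.from_tsv(str(path))
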