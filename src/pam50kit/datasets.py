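"""Packaged reference datasets.

Currently one: the published risk-of-recurrence worked example — seven
paired tumor samples assayed on both platforms, with their printed ROR /
ROR+PS scores and risk groups.  It is used to check the default risk-group
cutoffs and the risk-group discordance tally against printed results.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .concordance import PairedCalls
from .pam50 import Pam50Call


def load_reference_ror_table() -> pd.DataFrame:
    """Long-format table: sample_id, platform, ror_s/_group, ror_ps/_group."""
    ref = resources.files("pam50kit.data").joinpath("ror_reference_calls.json")
    with ref.open(encoding="utf-8") as fh:
        data = json.load(fh)
    return pd.DataFrame(data["samples"])


def reference_paired_calls() -> PairedCalls:
    """The worked example as PairedCalls (scores and groups only)."""
    table = load_reference_ror_table()

    def calls_for(platform: str) -> list[Pam50Call]:
        sub = table[table["platform"] == platform]
        return [
            Pam50Call(
                sample_id=row["sample_id"],
                ror_s=row["ror_s"], ror_s_group=row["ror_s_group"],
                ror_ps=row["ror_ps"], ror_ps_group=row["ror_ps_group"],
            )
            for _, row in sub.iterrows()
        ]

    return PairedCalls.from_call_lists(
        calls_for("nanostring"), calls_for("rnaseq"), "nanostring", "rnaseq"
    )
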