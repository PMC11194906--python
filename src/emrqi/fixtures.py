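"""Loaders for the packaged study fixtures.

The packaged panel is a 16-expert reconstruction of the published
consultation (7 very familiar / 9 relatively familiar experts; ten with a
maximal judgment basis, four intermediate, two low). The familiarity mapping
is a SYNTHETIC calibration — chosen so the panel reproduces the published
coefficients Cs = 0.88 and Ca = 0.90 exactly, since the authors' own score
tables are unpublished.
"""

from __future__ import annotations

import importlib.resources
import io

import pandas as pd
import yaml

from .delphi import ExpertProfile

__all__ = ["study_panel", "study_panel_mappings"]

_BASES = ("practical_experience", "theoretical_analysis", "peer_knowledge",
          "intuition")


def _read(name: str) -> str:
    return (importlib.resources.files("emrqi.data") / name).read_text()


def study_panel() -> list[ExpertProfile]:
    """The packaged 16-expert panel (profiles only; ratings unpublished)."""
    df = pd.read_csv(io.StringIO(_read("study_panel.csv")))
    return [
        ExpertProfile(
            expert_id=row["expert_id"],
            familiarity=row["familiarity"],
            judgment_basis={b: row[b] for b in _BASES},
        )
        for _, row in df.iterrows()
    ]


def study_panel_mappings() -> tuple[dict, dict]:
    """(familiarity mapping, judgment table) calibrated for the packaged panel."""
    cfg = yaml.safe_load(_read("study_panel_mappings.yaml"))
    return cfg["familiarity_scores"], cfg["judgment_table"]
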