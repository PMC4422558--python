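"""Embedded reference dataset: measured growth rates for E. coli K-12 NCM3722.

Steady-state exponential growth rates (1/h) in minimal medium with one or
two saturating carbon substrates, as printed in the source study's growth
table (averages over 2-4 experiments; between-experiment variability about
5%).  Fifteen pairs combine a "lower" substrate (succinate, pyruvate,
oxaloacetate — entering the TCA cycle or lower glycolysis) with an "upper"
substrate (mannose, xylose, glycerol, maltose, glucose) and are expected to
be co-utilized (group A).  Seven unique pairs couple glucose or glycerol
with other upper substrates (group B); inducer exclusion and
fructose-1,6-bisphosphate feedback give these pairs uptake interactions
outside the shared cAMP-Crp feedback, so they are expected to deviate from
the null model.  The glucose+glycerol pair, which the printed table shows
in both group-B columns, is stored once.
"""

from __future__ import annotations

from types import MappingProxyType

from .analysis import GrowthTable, PairObservation

__all__ = ["builtin_table1", "TABLE1_SINGLES", "TABLE1_PAIRS"]

#: Single-substrate growth rates, 1/h (printed values, two decimals).
TABLE1_SINGLES = MappingProxyType(
    {
        "succinate": 0.46,
        "pyruvate": 0.61,
        "oxaloacetate": 0.79,
        "glycerol": 0.63,
        "glucose": 0.85,
        "mannose": 0.42,
        "xylose": 0.61,
        "maltose": 0.67,
    }
)

#: (upper substrate, partner, measured mixed rate 1/h, group).
TABLE1_PAIRS = (
    ("mannose", "succinate", 0.64, "A"),
    ("mannose", "pyruvate", 0.70, "A"),
    ("mannose", "oxaloacetate", 0.87, "A"),
    ("xylose", "succinate", 0.71, "A"),
    ("xylose", "pyruvate", 0.80, "A"),
    ("xylose", "oxaloacetate", 0.88, "A"),
    ("glycerol", "succinate", 0.73, "A"),
    ("glycerol", "pyruvate", 0.85, "A"),
    ("glycerol", "oxaloacetate", 0.93, "A"),
    ("maltose", "succinate", 0.77, "A"),
    ("maltose", "pyruvate", 0.85, "A"),
    ("maltose", "oxaloacetate", 0.90, "A"),
    ("glucose", "succinate", 0.86, "A"),
    ("glucose", "pyruvate", 0.88, "A"),
    ("glucose", "oxaloacetate", 0.94, "A"),
    ("mannose", "glycerol", 0.65, "B"),
    ("xylose", "glycerol", 0.64, "B"),
    ("maltose", "glycerol", 0.70, "B"),
    ("glucose", "glycerol", 0.84, "B"),
    ("mannose", "glucose", 0.84, "B"),
    ("xylose", "glucose", 0.84, "B"),
    ("maltose", "glucose", 0.84, "B"),
)


def builtin_table1() -> GrowthTable:
    """The embedded reference growth table.

    Returns a fresh, validated :class:`~cocarbon.analysis.GrowthTable` with
    8 substrates, 15 group-A pairs and 7 group-B pairs.
    """
    return GrowthTable(
        singles=dict(TABLE1_SINGLES),
        pairs=tuple(
            PairObservation(substrate_1=s1, substrate_2=s2, rate=rate, group=group)
            for s1, s2, rate, group in TABLE1_PAIRS
        ),
    )
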