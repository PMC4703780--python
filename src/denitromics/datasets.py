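"""Small published reference datasets used by examples and tests.

These transcribe printed observations from the chemostat enrichment study
of denitrifying/fermentative communities from tidal-flat sediment (two
replicate experiments, 2011 and 2012, each at 10 and 25 degC) that this
package's analyses are designed around: the functional-gene inventory of
the 15 binned populations (bins A-O) and the influent/effluent chemistry of
the chemostats.
"""

from __future__ import annotations

from .massbalance import ChemostatState

#: Functional genes credited to each of the 15 bins (A-O) in the study's
#: guild classification.  Note on bin G (Photobacterium): the printed
#: per-contig gene table lists only pflB for this bin, but the study
#: classifies F-H as combined denitrifiers/fermentative (nitrous oxide
#: reduction plus pyruvate/formate lyase); this inventory follows that
#: classification and credits G with nosZ.
BIN_GENE_INVENTORY: dict[str, frozenset[str]] = {
    "A": frozenset({"nirK", "nosZ"}),
    "B": frozenset({"nosZ"}),
    "C": frozenset({"nirK"}),
    "D": frozenset({"nirS", "nosZ"}),
    "E": frozenset({"nirS", "nosZ"}),
    "F": frozenset({"nosZ", "pflB"}),
    "G": frozenset({"nosZ", "pflB"}),
    "H": frozenset({"nosZ", "pflB"}),
    "I": frozenset({"nosZ"}),
    "J": frozenset({"nirS", "nosZ"}),
    "K": frozenset({"nirS", "nosZ"}),
    "L": frozenset({"nirS", "nosZ"}),
    "M": frozenset({"nirS"}),
    "N": frozenset({"nosZ"}),
    "O": frozenset({"pflB"}),
}


def chemostat_2011_10c() -> ChemostatState:
    """The 2011 10 degC culture at its final operating point.

    Influent: 20 mM nitrite, 1 mM nitrate, 37.5 mM-C organic carbon
    (C:N = 1.8), 5.3 mM-N organic nitrogen.  Effluent ammonium 2.5 mM,
    measured protein 0.12 g/L, dilution rate eventually 0.08 volume
    changes/day.
    """
    return ChemostatState(
        influent_nitrite=20.0,
        influent_nitrate=1.0,
        influent_organic_carbon=37.5,
        influent_organic_n=5.3,
        effluent_ammonium=2.5,
        effluent_nitrite=0.0,
        measured_protein=0.12,
        dilution_rate=0.08,
        temperature=10.0,
    )


def chemostat_2011_25c() -> ChemostatState:
    """The 2011 25 degC culture: 28 mM-C influent carbon, complete nitrite
    and nitrate consumption, stable protein 0.14 g/L, 0.36 volume
    changes/day."""
    return ChemostatState(
        influent_nitrite=20.0,
        influent_nitrate=1.0,
        influent_organic_carbon=28.0,
        influent_organic_n=5.3,
        effluent_ammonium=2.5,
        effluent_nitrite=0.0,
        measured_protein=0.14,
        dilution_rate=0.36,
        temperature=25.0,
    )


#: measured steady-state protein concentrations, g/L, by (year, temperature)
MEASURED_PROTEIN: dict[tuple[int, int], float] = {
    (2011, 25): 0.14,
    (2011, 10): 0.12,
    (2012, 25): 0.095,
    (2012, 10): 0.10,
}
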