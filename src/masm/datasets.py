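"""Published influent characterisations used throughout the package.

Both tables come from sequential filtration / respirometric campaigns on
real wastewaters: a strong denim-processing textile effluent and a
domestic sewage, characterised with the modified (membrane-aware) COD
fractionation.  Values in mg COD/L.
"""

from .fractionation import CODFractionation

#: Denim-processing textile wastewater.
TEXTILE = CODFractionation(
    C_T1=1340.0, S_T1=965.0, X_T1=375.0,
    S_S1=280.0,
    S_HT1=460.0, S_H1=100.0, S_HC1=360.0,
    S_IT1=225.0, S_I1=135.0, S_IC1=90.0,
    X_ST1=360.0, X_S1=162.0, X_SS1=198.0,
    X_IT1=15.0, X_I1=7.0, X_IS1=8.0,
)

#: Domestic sewage.
DOMESTIC = CODFractionation(
    C_T1=415.0, S_T1=120.0, X_T1=295.0,
    S_S1=40.0,
    S_HT1=62.0, S_H1=15.0, S_HC1=47.0,
    S_IT1=18.0, S_I1=10.0, S_IC1=8.0,
    X_ST1=253.0, X_S1=113.0, X_SS1=140.0,
    X_IT1=42.0, X_I1=19.0, X_IS1=23.0,
)

PROFILES = {"textile": TEXTILE, "domestic": DOMESTIC}
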