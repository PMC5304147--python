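"""Controlled vocabulary for the twelve soybean seed isoflavones.

Soybean seeds accumulate isoflavones in four conjugation forms (free
aglycones, beta-glucosides, malonylglucosides, acetylglucosides) built on
three chemical skeletons (genistein G, daidzein D, glycitein GL).  The
twelve analytes and the eight derived totals used throughout the package
are defined here so every module shares one column ordering.
"""

from __future__ import annotations

# Canonical analyte ordering: conjugated forms first, aglycones last, matching
# typical HPLC elution reporting.  This ordering is also the tie-break order
# for ambiguous retention-time assignments.
ANALYTES: tuple[str, ...] = (
    "DG", "GLG", "GEG", "MD", "MGL", "AD", "AGL", "MG", "DE", "AG", "GLE", "GE",
)

# Conjugation forms
AGLYCONES: tuple[str, ...] = ("GE", "DE", "GLE")
GLUCOSIDES: tuple[str, ...] = ("GEG", "DG", "GLG")
MALONYLGLUCOSIDES: tuple[str, ...] = ("MG", "MD", "MGL")
ACETYLGLUCOSIDES: tuple[str, ...] = ("AG", "AD", "AGL")

# Skeleton families
G_TYPE: tuple[str, ...] = ("GE", "GEG", "AG", "MG")
D_TYPE: tuple[str, ...] = ("DE", "DG", "AD", "MD")
GL_TYPE: tuple[str, ...] = ("GLE", "GLG", "AGL", "MGL")

#: Derived totals: four conjugation-form sums, three skeleton sums, grand total.
DERIVED: tuple[str, ...] = ("T-e", "T-g", "T-m", "T-a", "To-G", "To-D", "To-GL", "total")

#: Mapping from each derived total (except "total") to its constituent analytes.
DERIVED_GROUPS: dict[str, tuple[str, ...]] = {
    "T-e": AGLYCONES,
    "T-g": GLUCOSIDES,
    "T-m": MALONYLGLUCOSIDES,
    "T-a": ACETYLGLUCOSIDES,
    "To-G": G_TYPE,
    "To-D": D_TYPE,
    "To-GL": GL_TYPE,
}

#: Conjugation-form partition of the total (used for percentage composition).
FORM_PARTITION: tuple[str, ...] = ("T-e", "T-g", "T-m", "T-a")
#: Skeleton-family partition of the total.
TYPE_PARTITION: tuple[str, ...] = ("To-G", "To-D", "To-GL")

#: All 20 variables entering the multivariate model (12 analytes + 8 totals).
ALL_VARIABLES: tuple[str, ...] = ANALYTES + DERIVED
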