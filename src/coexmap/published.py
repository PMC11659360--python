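"""Published whole-brain Ghsr/Cnr1 co-expression estimates.

Per-structure positive-cell counts from the published quantitative spatial
transcriptomic analysis of the Allen whole-mouse-brain atlas (10x +
MERFISH), used as worked-example inputs: the package's summary arithmetic
(percentages, roll-ups, headline shares) is checked against the values the
analysis printed. Only counts are stored; percentages are always recomputed.

Known caveats: a handful of printed percentage cells differ by 0.1 from
half-away-from-zero rounding of the printed counts (consistent with
truncation in the source), and some region brackets differ by 1-2 cells from
the sum of printed per-structure doubles; worked examples stick to the
self-consistent rows and regions.
"""

from __future__ import annotations

import pandas as pd

# Whole-dataset headline tallies (~4M cells deep atlas)
TOTAL_GHSR_POSITIVE = 16_425
TOTAL_CNR1_POSITIVE = 1_648_932
TOTAL_DOUBLE_POSITIVE = 9_554

# abbrev -> (region, structure name, n_ghsr, n_cnr1, n_double)
_STRUCTURES = [
    ("CA1", "HPF", "Field CA1", 2500, 212101, 2407),
    ("CA3", "HPF", "Field CA3", 2801, 70381, 1320),
    ("DG", "HPF", "Dentate gyrus", 3805, 51506, 1133),
    ("BLA", "CTXsp", "Basolateral amygdalar nucleus", 678, 47985, 629),
    ("PA", "CTXsp", "Posterior amygdalar nucleus", 468, 26537, 453),
    ("MEA", "STR", "Medial amygdalar nucleus", 1693, 43102, 800),
    ("BST", "PAL", "Bed nuclei of the stria terminalis", 647, 22080, 441),
    ("ARH", "HY", "Arcuate hypothalamic nucleus", 4437, 7648, 1247),
    ("DMH", "HY", "Dorsomedial nucleus of the hypothalamus", 634, 8990, 412),
    ("AHN", "HY", "Anterior hypothalamic nucleus", 662, 23413, 458),
    ("MM", "HY", "Medial mammillary nucleus", 1929, 7144, 431),
    ("MPN", "HY", "Medial preoptic nucleus", 602, 15675, 471),
    ("PMv", "HY", "Ventral premammillary nucleus", 549, 8154, 333),
    ("VMH", "HY", "Ventromedial hypothalamic nucleus", 1004, 29262, 729),
    ("PH", "HY", "Posterior hypothalamic nucleus", 627, 17403, 384),
    ("LHA", "HY", "Lateral hypothalamic area", 468, 23427, 341),
    ("ZI", "HY", "Zona incerta", 1274, 41399, 904),
    ("SCs", "MB", "Superior colliculus, sensory related", 551, 19710, 348),
    ("SNr", "MB", "Substantia nigra, reticular part", 1079, 9846, 580),
    ("VTA", "MB", "Ventral tegmental area", 2355, 2167, 332),
    ("MRN", "MB", "Midbrain reticular nucleus", 2011, 36820, 1408),
    ("SCm", "MB", "Superior colliculus, motor related", 1973, 79564, 1586),
    ("PAG", "MB", "Periaqueductal gray", 3663, 97288, 2669),
    ("PPN", "MB", "Pedunculopontine nucleus", 729, 10680, 613),
    ("PB", "P", "Parabrachial nucleus", 803, 14388, 708),
    ("PRNc", "P", "Pontine reticular nucleus, caudal part", 1120, 18550, 856),
    ("PRNr", "P", "Pontine reticular nucleus", 1004, 23325, 824),
    ("AP", "MY", "Area postrema", 431, 1618, 377),
    ("NTS", "MY", "Nucleus of the solitary tract", 795, 14017, 778),
    ("GRN", "MY", "Gigantocellular reticular nucleus", 845, 11060, 474),
    ("IRN", "MY", "Intermediate reticular nucleus", 759, 14177, 538),
    ("PARN", "MY", "Parvicellular reticular nucleus", 769, 16695, 618),
    ("MV", "MY", "Medial vestibular nucleus", 1438, 10581, 450),
]

# region -> published [listed double+ / total double+] bracket
REGION_BRACKETS = {
    "HPF": (4860, 5561),
    "CTXsp": (1082, 1747),
    "STR": (800, 1523),
    "PAL": (441, 1366),
    "HY": (5712, 8474),
    "MB": (7535, 10959),
    "P": (2387, 4712),
    "MY": (3236, 5245),
    "Other": (0, 1129),
}


def structure_counts() -> pd.DataFrame:
    """Published per-structure counts as a summary-shaped frame.

    Indexed by structure abbreviation with region_id, structure name and the
    est_a (Ghsr+), est_b (Cnr1+), est_ab (double+) columns the reporting
    functions expect. All listed structures passed the published selection
    filter; only selected structures are listed per region, so ``selected``
    is True throughout.
    """
    df = pd.DataFrame(
        _STRUCTURES,
        columns=["structure_id", "region_id", "name", "est_a", "est_b", "est_ab"],
    ).set_index("structure_id")
    df["selected"] = True
    return df
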