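"""Published summary statistics of the OSA MCI/nMCI study cohort.

These constants are the printed per-group summaries of the severe-OSA
cohort (51 patients with mild cognitive impairment, MCI; 48 without,
nMCI) that this package's statistics and simulation modules take as
inputs: demographic / polysomnography variables as mean +/- SD per
group, the sex contingency counts, and the per-group Gaussian
parameters of the ten selected region-mean zDC features.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GroupSummary",
    "FeatureStats",
    "N_MCI",
    "N_NMCI",
    "SEX_COUNTS",
    "DEMOGRAPHICS",
    "SELECTED_DC_FEATURES",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean and standard deviation of one variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if not self.sd > 0:
            raise ValueError(f"standard deviation must be > 0, got {self.sd}")


@dataclass(frozen=True)
class FeatureStats:
    """Per-group Gaussian parameters of one selected zDC feature."""

    name: str
    network: str
    mci_mean: float
    mci_sd: float
    nmci_mean: float
    nmci_sd: float

    def __post_init__(self) -> None:
        if not (self.mci_sd > 0 and self.nmci_sd > 0):
            raise ValueError(f"feature {self.name!r}: SDs must be > 0")


N_MCI = 51
N_NMCI = 48

#: Sex counts as (MCI male, MCI female, nMCI male, nMCI female).
SEX_COUNTS = (48, 3, 47, 1)

#: Continuous demographic / PSG variables: (MCI summary, nMCI summary).
DEMOGRAPHICS: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "age": (GroupSummary(N_MCI, 38.47, 7.93), GroupSummary(N_NMCI, 35.45, 8.76)),
    "education": (GroupSummary(N_MCI, 12.98, 2.33), GroupSummary(N_NMCI, 13.78, 3.21)),
    "bmi": (GroupSummary(N_MCI, 27.26, 3.06), GroupSummary(N_NMCI, 26.78, 4.20)),
    "neck_circumference": (
        GroupSummary(N_MCI, 41.17, 3.24),
        GroupSummary(N_NMCI, 39.95, 2.77),
    ),
    "waistline": (GroupSummary(N_MCI, 99.19, 6.92), GroupSummary(N_NMCI, 97.04, 15.18)),
    "ahi": (GroupSummary(N_MCI, 53.19, 23.12), GroupSummary(N_NMCI, 49.58, 19.23)),
    "nadir_spo2": (GroupSummary(N_MCI, 71.25, 12.52), GroupSummary(N_NMCI, 68.31, 12.52)),
    "mean_spo2": (GroupSummary(N_MCI, 92.38, 3.57), GroupSummary(N_NMCI, 91.82, 5.13)),
    "total_sleep_time": (
        GroupSummary(N_MCI, 366.05, 112.36),
        GroupSummary(N_NMCI, 379.20, 77.78),
    ),
    "sleep_efficiency": (
        GroupSummary(N_MCI, 80.01, 22.20),
        GroupSummary(N_NMCI, 85.74, 12.14),
    ),
    "n1": (GroupSummary(N_MCI, 28.94, 17.26), GroupSummary(N_NMCI, 25.16, 16.58)),
    "n2": (GroupSummary(N_MCI, 39.32, 12.68), GroupSummary(N_NMCI, 43.16, 15.09)),
    "n3": (GroupSummary(N_MCI, 19.58, 14.68), GroupSummary(N_NMCI, 21.39, 15.68)),
    "rem": (GroupSummary(N_MCI, 15.45, 9.90), GroupSummary(N_NMCI, 12.63, 8.71)),
    "spo2_below_90": (GroupSummary(N_MCI, 24.34, 20.02), GroupSummary(N_NMCI, 23.23, 16.36)),
    "moca": (GroupSummary(N_MCI, 22.23, 2.61), GroupSummary(N_NMCI, 27.27, 1.16)),
}

#: The ten AAL region-mean zDC features selected by correlation pruning +
#: LASSO in the study, with their per-group Gaussian parameters.  Region
#: names follow the AAL-116 convention (vermis/cerebellar regions included).
SELECTED_DC_FEATURES: tuple[FeatureStats, ...] = (
    FeatureStats("Olfactory_R", "DMN", -0.095, 0.292, -0.187, 0.245),
    FeatureStats("Cingulum_Ant_L", "DMN", 0.174, 0.336, 0.293, 0.385),
    FeatureStats("Pallidum_L", "basal_node", -0.110, 0.383, 0.088, 0.477),
    FeatureStats("Heschl_L", "DMN", 0.260, 0.412, 0.489, 0.351),
    FeatureStats("Cerebelum_Crus1_R", "cerebellum", 0.059, 0.280, -0.088, 0.289),
    FeatureStats("Cerebelum_4_5_L", "cerebellum", -0.027, 0.221, 0.151, 0.239),
    FeatureStats("Vermis_1", "cerebellum", -0.386, 0.348, -0.258, 0.272),
    FeatureStats("Vermis_6", "cerebellum", -0.123, 0.280, 0.001, 0.335),
    FeatureStats("Vermis_8", "cerebellum", -0.419, 0.310, -0.286, 0.295),
    FeatureStats("Vermis_10", "cerebellum", -0.399, 0.304, -0.503, 0.284),
)
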