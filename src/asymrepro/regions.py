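"""Cortical region and measure naming.

Measures follow the "<region>_<metric>" convention over the 34
Desikan-Killiany regions plus "fullhemi" for the hemisphere-level averages,
with metric in {thickness, area}: 70 measures in total.
"""

from __future__ import annotations

DESIKAN_KILLIANY_REGIONS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

METRICS = ("thickness", "area")
FULL_HEMISPHERE = "fullhemi"


def measure_id(region: str, metric: str) -> str:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return f"{region}_{metric}"


def all_measure_ids() -> list[str]:
    """The 70 measure identifiers: 34 regions x 2 metrics + 2 hemisphere-level."""
    ids = [measure_id(r, m) for m in METRICS for r in DESIKAN_KILLIANY_REGIONS]
    ids += [measure_id(FULL_HEMISPHERE, m) for m in METRICS]
    return ids


def split_measure_id(measure: str) -> tuple[str, str]:
    """(region, metric) from a measure id; raises on malformed names."""
    region, sep, metric = measure.rpartition("_")
    if not sep or metric not in METRICS:
        raise ValueError(
            f"measure id {measure!r} does not match '<region>_<metric>' with "
            f"metric in {METRICS}"
        )
    return region, metric


def metric_of(measure: str) -> str:
    return split_measure_id(measure)[1]


def region_class_of(measure: str) -> str:
    """'hemisphere' for the fullhemi measures, else 'regional'."""
    region, _ = split_measure_id(measure)
    return "hemisphere" if region == FULL_HEMISPHERE else "regional"
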