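"""Cross-method identification comparison.

Three identification routes can be run on the same isolates — reduced-
representation genotyping (``reduced_rep``), whole-genome alignment
(``wgs``) and 16S rRNA gene alignment (``rrna16s``) — each reporting one or
more equal-best matching genomes per sample. This module computes the
agreement statistics between a test method and a reference method:

* *agree* — the species of the test method's best-match set intersects the
  reference method's;
* *differ* — no species overlap;
* *ambiguous* — the test method reports more than one equal-best match
  (orthogonal to agree/differ).

Species equality is at the binomial level: strain designations and
accession tails are stripped, so "Geobacillus vulcani PSS1" and
"Geobacillus vulcani PSS1 N685" compare equal, while "Anoxybacillus sp.
103" keeps its open nomenclature as "Anoxybacillus sp.".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "MethodCall",
    "normalize_species",
    "load_calls",
    "agreement_stats",
    "packaged_method_calls",
    "packaged_identifications",
]

METHODS = ("reduced_rep", "wgs", "rrna16s")


@dataclass(frozen=True)
class MethodCall:
    """All equal-best matches one method reports for one sample."""

    sample_id: str
    method: str
    matches: tuple[tuple[str, str], ...]  # (genome_label, species)

    def __post_init__(self) -> None:
        if not self.matches:
            raise ValueError(f"{self.sample_id}/{self.method}: an identified sample needs >= 1 match")

    @property
    def species_set(self) -> set[str]:
        return {species for _, species in self.matches}


def normalize_species(label: str) -> str:
    """Binomial species name from a best-match genome label."""
    tokens = label.replace("_", " ").split()
    if not tokens:
        return label
    if len(tokens) == 1:
        return tokens[0]
    second = tokens[1].rstrip(".").lower()
    if second == "sp":
        return f"{tokens[0]} sp."
    # drop strain designations / accession tails after the epithet
    epithet = re.sub(r"[^a-z-]", "", tokens[1].lower())
    return f"{tokens[0]} {epithet}" if epithet else tokens[0]


def load_calls(path_or_df) -> list[MethodCall]:
    """Load method calls from CSV (sample_id, method, rank, genome_label[, species])."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    required = {"sample_id", "method", "genome_label"}
    if missing := required - set(df.columns):
        raise ValueError(f"method-call table missing columns: {sorted(missing)}")
    if "species" not in df.columns:
        df = df.assign(species=df["genome_label"].map(normalize_species))
    calls = []
    for (sample, method), grp in df.groupby(["sample_id", "method"], sort=False):
        if "rank" in grp.columns:
            grp = grp.sort_values("rank")
        calls.append(MethodCall(sample, method, tuple(zip(grp["genome_label"], grp["species"]))))
    return calls


def agreement_stats(calls: list[MethodCall], reference_method: str, test_method: str) -> dict[str, float]:
    """Percent agreement/difference/ambiguity of a test method vs a reference.

    Every sample must carry a call for both methods. Percentages are over
    the sample count, reported to one decimal.
    """
    by_sample: dict[str, dict[str, MethodCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, {})[c.method] = c
    n_agree = n_differ = n_ambiguous = 0
    for sample, methods in sorted(by_sample.items()):
        for m in (reference_method, test_method):
            if m not in methods:
                raise ValueError(f"sample {sample!r} has no call for method {m!r}")
        ref, test = methods[reference_method], methods[test_method]
        if test.species_set & ref.species_set:
            n_agree += 1
        else:
            n_differ += 1
        if len(test.matches) > 1:
            n_ambiguous += 1
    n = len(by_sample)
    if n == 0:
        raise ValueError("no samples to compare")
    return {
        "n_samples": n,
        "percent_agree_species": round(100.0 * n_agree / n, 1),
        "percent_differ": round(100.0 * n_differ / n, 1),
        "percent_ambiguous": round(100.0 * n_ambiguous / n, 1),
    }


def _data_path(name: str) -> Path:
    return Path(str(resources.files("rrident").joinpath("data", name)))


def packaged_method_calls() -> list[MethodCall]:
    """The packaged eight-isolate three-method comparison table."""
    return load_calls(_data_path("method_calls_wgs_comparison.csv"))


def packaged_identifications() -> pd.DataFrame:
    """The packaged per-isolate identification summary (closest match,
    average % identity, NSD, genome coverage %) for the 99 isolates."""
    return pd.read_csv(_data_path("isolate_identifications.csv"))
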