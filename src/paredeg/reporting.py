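"""T-plots, target-table reports, and packaged reference tables.

The package ships machine-readable transcriptions of the published
mulberry degradome target tables — the significant (P <= 0.05) miRNA-mRNA
pairs of the contrast (CL, 72 rows) and drought (DL, 63 rows) libraries —
used as ground truth for tally checks, plus the whole-library per-category
target totals.

A T-plot (target plot) shows degradome tag abundance along a transcript
with the predicted cleavage site marked; it is the standard visual
evidence for a degradome-supported cleavage call.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Optional

import pandas as pd

from .cleavage_caller import DegradomeProfile, TargetRecord

FIXTURE_FILES = {"CL": "targets_cl.tsv", "DL": "targets_dl.tsv"}

_FIXTURE_DTYPES = {
    "miRNA": str, "Target": str, "C.Site": int, "Location": str,
    "Score": float, "Category": int, "TP100M": float, "P-Value": float,
}

_FAMILY_RE = re.compile(r"^(mno-miRn?\d+)")


def _data_path(name: str):
    return resources.files("paredeg.data").joinpath(name)


def load_fixture(library: str) -> pd.DataFrame:
    """Load the packaged target table of one library ('CL' or 'DL')."""
    try:
        fname = FIXTURE_FILES[library.upper()]
    except KeyError:
        raise ValueError(f"unknown library label {library!r}") from None
    with resources.as_file(_data_path(fname)) as path:
        df = pd.read_csv(path, sep="\t")
    expected = list(_FIXTURE_DTYPES)
    if list(df.columns) != expected:
        raise ValueError(f"malformed fixture {fname}: columns {list(df.columns)}")
    for i, row in df.iterrows():
        for col in ("C.Site", "Category"):
            if pd.isna(row[col]) or int(row[col]) != row[col]:
                raise ValueError(f"malformed fixture {fname}: row {i + 1}")
    return df.astype(_FIXTURE_DTYPES)


def load_category_totals() -> pd.DataFrame:
    """Whole-library per-category target totals (all called targets, not
    just the significant subset)."""
    with resources.as_file(_data_path("category_totals.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def mirna_family(name: str) -> str:
    """Family of a miRNA name: the numbered stem with variant letters,
    copy segments and arm suffixes stripped (mno-miR156c -> mno-miR156,
    mno-miRn74a-1-3p -> mno-miRn74)."""
    m = _FAMILY_RE.match(name)
    if not m:
        return name
    return m.group(1)


def summarize_fixture(fixture: pd.DataFrame,
                      group_by: str = "category") -> pd.Series:
    """Grouped pair counts by 'category' or 'mirna_family'."""
    if fixture.empty:
        return pd.Series(dtype=int)
    if group_by == "category":
        return fixture.groupby("Category").size()
    if group_by == "mirna_family":
        return fixture["miRNA"].map(mirna_family).value_counts().sort_index()
    raise ValueError(f"unknown group_by {group_by!r}")


def render_tplot(profile: DegradomeProfile, record: TargetRecord,
                 mode: str = "tsv", path=None,
                 annotation: Optional[str] = None):
    """Render one target's T-plot as a TSV table or a figure file.

    TSV mode returns a DataFrame of (position, abundance, is_site) and
    writes it when ``path`` is given; figure mode writes a plot with the
    cleavage site highlighted (``annotation`` text, e.g. the duplex
    pairing diagram, is placed on the figure).
    """
    if not profile.counts:
        raise ValueError("empty profile: nothing to plot")
    if record.site not in profile.counts:
        raise ValueError(
            f"record site {record.site} unsupported by the profile")
    positions = sorted(profile.counts)
    df = pd.DataFrame({
        "position": positions,
        "abundance": [profile.counts[p] for p in positions],
        "is_site": [p == record.site for p in positions]})
    if mode == "tsv":
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df
    if mode == "figure":
        if path is None:
            raise ValueError("figure mode requires a path")
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.vlines(df["position"], 0, df["abundance"], color="0.4", lw=1)
        site_count = profile.counts[record.site]
        ax.vlines([record.site], 0, [site_count], color="red", lw=2)
        ax.annotate(f"{record.mirna_id} @ {record.site} ({site_count})",
                    xy=(record.site, site_count),
                    xytext=(record.site, site_count * 1.05),
                    color="red", fontsize=8, ha="center")
        if annotation:
            ax.text(0.99, 0.95, annotation, transform=ax.transAxes,
                    fontsize=7, family="monospace", ha="right", va="top")
        ax.set_xlabel(f"position on {profile.transcript_id} (nt)")
        ax.set_ylabel("raw tag count")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
    raise ValueError(f"unknown mode {mode!r}")


def records_to_frame(records) -> pd.DataFrame:
    """Target records as a table with the standard column set."""
    return pd.DataFrame(
        [{"miRNA": r.mirna_id, "Target": r.transcript_id, "C.Site": r.site,
          "Location": r.location, "Score": round(r.score, 1),
          "Category": r.category, "TP100M": r.tp100m,
          "P-Value": r.p_value} for r in records],
        columns=list(_FIXTURE_DTYPES))


def accounting_to_frame(acc) -> pd.DataFrame:
    """Library accounting as a one-row summary table."""
    return pd.DataFrame([{
        "raw_tags": acc.raw_tags,
        "clean_tags": acc.clean_tags,
        "clean_pct": round(acc.clean_fraction * 100, 2),
        "filtered_N": acc.filtered_n,
        "filtered_low_quality": acc.filtered_low_quality,
        "polyN": acc.polyn_count,
        "unique_tags": acc.unique_tag_count,
    }])
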