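"""Burst identification and burst-wise multiparameter analysis."""

from .search import sliding_window_burst_search, burst_region_mask
from .table import BurstTable
from .filters import alex_2cde, kernel_density
from .corrections import CorrectionSet, correct_and_score
from .lifetime import mle_lifetime
from .anisotropy import burst_anisotropy, perrin, perrin_fit
from .fret_lines import FretLine, static_fret_line, dynamic_fret_line
from .histograms import multiparameter_histograms, plot_multiparameter

__all__ = [
    "sliding_window_burst_search",
    "burst_region_mask",
    "BurstTable",
    "alex_2cde",
    "kernel_density",
    "CorrectionSet",
    "correct_and_score",
    "mle_lifetime",
    "burst_anisotropy",
    "perrin",
    "perrin_fit",
    "FretLine",
    "static_fret_line",
    "dynamic_fret_line",
    "multiparameter_histograms",
    "plot_multiparameter",
    "analyze_bursts",
]


def analyze_bursts(stream, corrections=None, window_us=500.0,
                   min_per_window=5, min_total=50, alex2cde_max=12.0,
                   kde_time_constant_us=100.0, lifetimes=True,
                   anisotropies=True):
    """Full burst pipeline: search, ALEX-2CDE filter, corrections, lifetimes.

    Returns ``(table, summary)`` where ``summary`` counts the bursts
    surviving each stage.
    """
    table = sliding_window_burst_search(stream, window_us, min_per_window,
                                        min_total)
    summary = {"searched": len(table)}
    table.compute_alex_2cde(kde_time_constant_us)
    table = table.filter_alex_2cde(alex2cde_max)
    summary["alex_2cde_pass"] = len(table)
    if corrections is not None:
        table.compute_corrections(corrections)
        summary["defined_E"] = int((~table.df["undefined"]).sum())
    if lifetimes:
        table.compute_lifetimes()
    if anisotropies:
        g = corrections.g_factor if corrections is not None else 1.0
        table.compute_anisotropies(g)
    return table, summary
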