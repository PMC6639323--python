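"""Bundled reference signature catalog (synthetic stand-in).

The real COSMIC/PCAWG SBS catalog is license-encumbered and not redistributed here;
``reference_sbs_synthetic.tsv`` is a *synthetic*, stylized stand-in built by
:func:`synthetic_reference_signatures`. Each profile reproduces the hallmark
channel structure of the named mutational process (e.g. APOBEC C>T/C>G at TpC for
SBS2/SBS13, C>T at NpCpG for the clock-like SBS1, dipyrimidine C>T for the UVR
signature SBS7a) but the exact probabilities are not COSMIC's. Replace the file
with a genuine catalog (same TSV layout: channels x signatures) for real analyses.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .signatures import CHANNELS_96, parse_channel

#: hallmark channel emphases: signature -> list of (predicate on (ref, alt, 5', 3'), weight)
_HALLMARKS = {
    # clock-like deamination of methylated CpG
    "SBS1": [(lambda r, a, f, t: (r, a, t) == ("C", "T", "G"), 30.0)],
    # APOBEC cytidine deamination at TpC
    "SBS2": [(lambda r, a, f, t: (r, a, f) == ("C", "T", "T"), 40.0)],
    "SBS13": [(lambda r, a, f, t: (r, a, f) == ("C", "G", "T"), 40.0)],
    # flat clock-like signature
    "SBS5": [(lambda r, a, f, t: True, 1.0),
             (lambda r, a, f, t: (r, a) == ("T", "C"), 1.5)],
    # UVR: C>T at dipyrimidine sites (5' C or T)
    "SBS7a": [(lambda r, a, f, t: (r, a) == ("C", "T") and f in ("C", "T"), 25.0)],
    # T>G at CpTpT, gastric/oesophageal
    "SBS17b": [(lambda r, a, f, t: (r, a, f) == ("T", "G", "C"), 45.0)],
    # HR-deficiency-like flat profile with mild C>G lean
    "SBS3": [(lambda r, a, f, t: True, 1.0),
             (lambda r, a, f, t: (r, a) == ("C", "G"), 0.8)],
    # platinum exposure
    "SBS31": [(lambda r, a, f, t: (r, a) == ("C", "T") and f == "C", 18.0),
              (lambda r, a, f, t: (r, a) == ("T", "A"), 4.0)],
    "SBS35": [(lambda r, a, f, t: (r, a) == ("C", "A"), 8.0),
              (lambda r, a, f, t: (r, a) == ("C", "T") and f == "C", 8.0)],
    # UV-indirect
    "SBS38": [(lambda r, a, f, t: (r, a) == ("C", "A") and f == "T", 20.0)],
    # unknown aetiology, C>G enriched at TpC/ApC
    "SBS39": [(lambda r, a, f, t: (r, a) == ("C", "G") and f in ("A", "T"), 12.0)],
    # flat, unknown aetiology
    "SBS40": [(lambda r, a, f, t: True, 1.0)],
}


def synthetic_reference_signatures(noise: float = 0.02, seed: int = 20240917) -> pd.DataFrame:
    """Build the stylized stand-in catalog: signatures x 96 channels, rows sum to 1.

    Deterministic: each profile is its hallmark weights plus a small uniform floor
    and a reproducible jitter, normalized to a probability distribution.
    """
    rng = np.random.default_rng(seed)
    parsed = [parse_channel(c) for c in CHANNELS_96]
    rows = {}
    for sig, rules in _HALLMARKS.items():
        w = np.full(96, 0.05)
        for predicate, weight in rules:
            for i, (r, a, f, t) in enumerate(parsed):
                if predicate(r, a, f, t):
                    w[i] += weight
        w = w * (1.0 + noise * rng.standard_normal(96))
        w = np.clip(w, 1e-6, None)
        rows[sig] = w / w.sum()
    return pd.DataFrame(rows, index=list(CHANNELS_96)).T


def load_reference_signatures(path: str | None = None) -> pd.DataFrame:
    """Load a reference catalog (signatures x 96 channels, rows sum to 1).

    Without ``path``, loads the bundled synthetic stand-in
    ``reference_sbs_synthetic.tsv``. The TSV layout is channels as rows,
    signatures as columns (the layout reference catalogs ship in).
    """
    if path is None:
        ref = importlib.resources.files("soma").joinpath("data/reference_sbs_synthetic.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CHANNELS_96):
        raise ValueError("reference catalog rows must be the 96 channels in canonical order")
    return df.T
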