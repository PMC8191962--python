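"""Published reference top-20 importance lists for the 130-patient CRT cohort.

These are the two top-20 feature lists reported for the clinical cohort —
one from the out-of-bag random-forest analysis, one from the combined
wrapper/filter (CWF) consensus — transcribed into this package's feature
name grammar (``<family>_<view>_<qualifier>``).  They serve as fixed
reference inputs for the view-census and ranking-overlap summaries; the
underlying patient-level data are not public.
"""

from __future__ import annotations

#: OOB top-20, most important first.
PUBLISHED_OOB_TOP20: tuple[str, ...] = (
    "Iavc_2ch_BI",
    "Iavc_2ch_std",
    "E_4ch_BS",
    "Tpeak_3ch_AAs",
    "Ipeak_4ch_std",
    "Tpeak_4ch_MS",
    "Tpeak_2ch_MI",
    "Ipeak_4ch_AS",
    "E_3ch_AAs",
    "P_3ch_MAs",
    "E_4ch_AS",
    "Ipeak_4ch_BL",
    "E_4ch_MS",
    "E_4ch_L",
    "Tpeak_4ch_mean",
    "Ipeak_4ch_L",
    "Iavc_4ch_BL",
    "Tpeak_4ch_BS",
    "E_2ch_mean",
    "Tavc_2ch",
)

#: CWF top-20, most important first.
PUBLISHED_CWF_TOP20: tuple[str, ...] = (
    "Iavc_2ch_BI",
    "P_3ch_AAs",
    "E_2ch_AA",
    "Tpeak_4ch_mean",
    "E_4ch_MS",
    "E_4ch_BS",
    "E_2ch_mean",
    "P_4ch_AS",
    "Tpeak_2ch_MI",
    "Ipeak_2ch_AA",
    "Iavc_4ch_L",
    "Iavc_4ch_AS",
    "Ipeak_4ch_L",
    "E_2ch_BI",
    "Tpeak_3ch_AAs",
    "E_2ch_I",
    "E_2ch_MA",
    "P_3ch_MAs",
    "Tpeak_4ch_MS",
    "E_2ch_MI",
)
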