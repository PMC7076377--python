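"""Bundled reference measurements for worked examples and replay checks.

Two small published tables accompany the package as inputs:

* the differentially edited mitochondrial sites reported for the
  *mef37-1*, *pgn* and *otp90* mutants — WT and mutant editing extents
  (percent, one decimal) with the reported integer-percent dEE and the
  Bonferroni-adjusted p-value;
* the candidate-rank pairs for the 45 editing sites associated with the
  18 characterized E+ PPR proteins — the rank of each site among all 795
  known editing sites and its rank after restricting candidates to the
  DYW2-dependent sites.

Reported extents are rounded to 0.1 percentage point, so a dEE
recomputed from them can differ by a few integer percent from the
reported dEE (which was computed on unrounded extents); see
:func:`delta_ee_bounds_from_printed` for the achievable interval.
"""

from __future__ import annotations

import io

import pandas as pd

_DIFFERENTIAL_TSV = """\
mutant\tsite_id\tname\tee_wt\tee_mut\tdelta_ee_reported\tp_adj
mef37-1\tM17869\tccmB_566\t90.5\t6.6\t-93\t0.000
mef37-1\tM17884\tccmB_551\t96.4\t1.4\t-99\t0.000
mef37-1\tM23217\trps3_1470\t72.4\t0.0\t-100\t0.000
mef37-1\tM49473\tatp6_71\t0.6\t0.0\t-100\t0.002
mef37-1\tM189896\tccmFc_414\t3.5\t0.0\t-100\t0.002
mef37-1\tM215126\tnad4_437\t98.1\t48.5\t-51\t0.000
mef37-1\tM219378\tmttb_387\t42.8\t5.7\t-87\t0.000
mef37-1\tM308476\tccmC_179\t95.7\t0.9\t-99\t0.000
mef37-1\tM362007\tnad4L_trailer_72\t90.2\t1.8\t-98\t0.000
mef37-1\tM362343\tatp4_138\t92.1\t1.3\t-99\t0.000
mef37-1\tM362349\tatp4_144\t7.7\t27.3\t253\t0.000
pgn\tM8348\tcox2_742\t99.6\t0.0\t-100\t0.000
pgn\tM165765\tnad6_leader_-73\t84.4\t0.2\t-100\t0.000
otp90\tM17839\tccmB_596\t81.8\t23.0\t-72\t0.000
otp90\tM18355\tccmB_80\t83.9\t5.9\t-93\t0.000
otp90\tM59321\tnad1_500\t73.9\t0.0\t-100\t0.000
otp90\tM191687\tccmFc_1246\t67.6\t12.7\t-81\t0.000
otp90\tM209816\tnad4_194\t9.6\t14.7\t54\t0.027
otp90\tM209909\tnad4_111\t68.9\t84.6\t23\t0.000
otp90\tM219657\tmttb_108\t4.8\t0.2\t-95\t0.006
otp90\tM219668\tmttb_97\t81.6\t1.9\t-98\t0.000
otp90\tM233590\tmatR_1950\t3.1\t7.8\t149\t0.049
otp90\tM308481\tccmC_184\t83.3\t5.6\t-93\t0.000
otp90\tM329728\tcox3_trailer_248\t0.6\t0.0\t-92\t0.000
otp90\tM362007\tnad4L_trailer_72\t86.9\t92.6\t7\t0.000
"""

_RANK_PAIRS_TSV = """\
protein\tsite_id\tname\trank_full\trank_dyw2
AEF1\tM26928\tnad5_1580\t1\t1
AEF1\tP12707\tatpF_92\t18\t6
AHG11\tM215187\tnad4_376\t1\t1
CLB19\tP69942\tclpP_559\t2\t2
CLB19\tP78691\trpoA_200\t5\t5
COD1\tM6961\tcox2_698\t6\t2
COD1\tM6516\tcox2_253\t8\t4
COD1\tM209881\tnad4_1129\t34\t14
CRR21\tP116785\tndhD_383\t1\t1
CWM1\tM235780\tnad5_598\t2\t1
CWM1\tM18007\tccmB_428\t4\t2
CWM1\tM308760\tccmC_463\t12\t6
GRS1\tM165940\tnad6_103\t1\t1
GRS1\tM361691\tnad4L_55\t2\t2
GRS1\tM160356\trps4_377\t33\t14
GRS1\tM83057\tnad1_265\t109\t41
MEF12\tM235556\tnad5_374\t1\t1
MEF13\tM189532\tccmFc_50\t1\t1
MEF13\tM189897\tccmFc_415\t2\t2
MEF13\tM161857\tnad2_59\t3\t3
MEF13\tM215405\tnad4_158\t4\t4
MEF13\tM28242\tnad5_1916\t5\t5
MEF13\tM330460\tcox3_314\t6\t6
MEF13\tM27013\tnad5_1665\t47\t21
MEF21\tM330517\tcox3_257\t1\t1
MEF25\tM83014\tnad1_308\t12\t7
MEF37\tM215126\tnad4_437\t1\t1
MEF37\tM17884\tccmB_551\t3\t2
MEF37\tM17869\tccmB_566\t12\t5
MEF37\tM23217\trps3_1470\t17\t8
MEF37\tM308476\tccmC_179\t46\t22
MEF37\tM362343\tatp4_138\t57\t24
MEF37\tM219378\tmttB_387\t70\t31
OTP72\tM23724\trpl16_440\t1\t1
OTP80\tP86055\trpl23_89\t1\t1
PGN\tM8348\tcox2_742\t1\t1
PGN\tM165765\tnad6_leader_-73\t2\t2
SLG1\tM288290\tnad3_250\t1\t1
SLO1\tM215114\tnad4_449\t1\t1
SLO1\tM24992\tnad9_328\t2\t2
SLO2\tM241512\tnad7_739\t2\t1
SLO2\tM219621\tmttB_144\t4\t2
SLO2\tM361746\tnad4L_110\t76\t23
SLO2\tM219099\tmttB_666\t139\t47
SLO2\tM219620\tmttB_145\t177\t65
"""


def mutant_differential_sites() -> pd.DataFrame:
    """Reported differential-editing measurements for the three mutants."""
    return pd.read_csv(io.StringIO(_DIFFERENTIAL_TSV), sep="\t")


def eplus_rank_pairs() -> pd.DataFrame:
    """Reported (full, DYW2-filtered) candidate ranks for E+ protein targets."""
    return pd.read_csv(io.StringIO(_RANK_PAIRS_TSV), sep="\t")


def delta_ee_bounds_from_printed(
    ee_wt: float, ee_mut: float, precision: float = 0.05
) -> tuple[float, float]:
    """Interval of dEE values achievable from rounded printed extents.

    Printed extents are rounded to one decimal (percent), so the true
    extents lie within ``precision`` (= 0.05) percentage points of the
    printed values.  Returns the (min, max) of
    100 * (mut - wt) / wt over that box, clipping extents to [0, 100]
    and the ratio's denominator away from 0.
    """
    wt_lo = max(ee_wt - precision, 1e-9)
    wt_hi = max(ee_wt + precision, 1e-9)
    mut_lo = max(ee_mut - precision, 0.0)
    mut_hi = min(ee_mut + precision, 100.0)
    corners = [
        100.0 * (m - w) / w
        for w in (wt_lo, wt_hi)
        for m in (mut_lo, mut_hi)
    ]
    return min(corners), max(corners)
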