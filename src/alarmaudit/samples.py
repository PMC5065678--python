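"""Miniature sample audit-log exports bundled with the package.

These are small, de-identified exhibits in the central station's export
dialect (MRNs masked to zeros), used by the documentation, the test
suite, and the demo commands.  ``SAMPLE_UNIT_LOG`` shows a typical
minute of a 20-bed cardiac ICU: yellow and red numerical alarms with
their sound events, a sub-second alarm whose end row precedes its
generation row, a soft INOP, and a spread of clinician actions
including two alarm-limit changes.  ``SAMPLE_DESAT_LIMITS`` collects
desaturation alarms whose programmed lower limits range from a safe 90%
down to a plainly unsafe 50%.  ``SAMPLE_HR_PRIORITY_PAIR`` shows the
same heart-rate condition alarming at two different priorities.
"""

from __future__ import annotations

import io

from .io import read_audit_log
from .records import AuditRecord

__all__ = ["SAMPLE_UNIT_LOG", "SAMPLE_DESAT_LIMITS",
           "SAMPLE_HR_PRIORITY_PAIR", "load_sample_unit_log",
           "load_sample_desat_limits", "load_sample_hr_priority_pair"]

SAMPLE_UNIT_LOG = """\
Date\tBed label\tMRN\tAlarm and Action\tDevice name
4/20/14 0:00:00\t9115-S1\t0000000\t**PAPd 18 >16 Ended.\tPIIC iX: ixsurv006
4/20/14 0:00:00\t9115-S1\t0000000\t**PAPd 18 >16 Generated.\tPIIC iX: ixsurv006
4/20/14 0:00:00\t9115-S1\t0000000\tYellow alarm sound played.\tPIIC iX: ixsurv006
4/20/14 0:00:02\t9115-S1\t0000000\t**ABPs 170 >160 Generated.\tPIIC iX: ixsurv006
4/20/14 0:01:05\t9123-S1\t0000000\t***Desat 70 < 78 Generated.\tPIIC iX: ixsurv005
4/20/14 0:01:05\t9123-S1\t0000000\tRed alarm sound played.\tPIIC iX: ixsurv005
4/20/14 0:01:12\t9123-S1\t0000000\t***Desat 73 < 78 ended.\tPIIC iX: ixsurv005
4/20/14 0:01:16\t9115-S1\t0000000\t**ABPs 168 >160 Ended.\tPIIC iX: ixsurv006
4/20/14 0:01:20\t9123-S1\t0000000\tSilence.\tPIIC iX: ixsurv005
4/20/14 0:01:40\t9115-S1\t0000000\t*Multiform PVCs Generated.\tPIIC iX: ixsurv006
4/20/14 0:01:40\t9115-S1\t0000000\tResume All Alarms.\tPIIC iX: ixsurv006
4/20/14 0:01:40\t9117-S1\t0000000\t**RR 37 >30 Ended.\tPIIC iX: ixsurv006
4/20/14 0:01:40\t9111-S1\t0000000\tPatient transferred to 9035-S1.\tPIIC iX: ixsurv006
4/20/14 0:01:42\t9095-S1\t0000000\tPatient category set to Adult.\tPIIC iX: ixsurv006
4/20/14 0:01:43\t9090-S1\t0000000\tPacer algorithm set to Pacer Algorithm On.\tPIIC iX: ixsurv006
4/20/14 0:01:44\t9123-S1\t0000000\tECG Leads Off Generated.\tPIIC iX: ixsurv006
4/20/14 0:01:44\t9123-S1\t0000000\tINOP sound played.\tPIIC iX: ixsurv006
4/20/14 0:01:59\t9123-S1\t0000000\tECG Leads Off Ended.\tPIIC iX: ixsurv006
4/20/14 0:02:00\t9093-S1\t0000000\tEquipment Offline.\tPIIC iX: ixsurv006
4/20/14 0:02:00\t9115-S1\t0000000\t**PAPd 18 >16 Generated.\tPIIC iX: ixsurv006
4/20/14 0:02:00\t9093-S1\t0000000\tEquipment Online.\tPIIC iX: ixsurv006
4/20/14 0:02:00\t9085-S1\t0000000\tST: Al. Limits ST-V2 High: 1.6 ST-V2 Low: −1.6.\tPIIC iX: ixsurv006
4/20/14 0:02:00\t9117-S1\t0000000\tArrhythmia Off.\tPIIC iX: ixsurv006
4/20/14 0:02:02\t9115-S1\t0000000\tPause All Alarms.\tPIIC iX: ixsurv006
4/20/14 0:02:02\t9075-S1\t0000000\tArrhy: Missed Beat Off.\tPIIC iX: ixsurv006
4/20/14 0:03:00\t9085-S1\t0000000\tSpO_2_: Desat Limit 78.\tPIIC iX: ixsurv006
"""

SAMPLE_DESAT_LIMITS = """\
Date\tBed label\tAlarm and Action\tDevice name
7/16/14 4:57\t9101-S1\t*** Desat 89 < 90 Generated.\tPIIC iX: ixsurv007
7/28/14 21:44\t9115-S1\t*** Desat 87 < 88 Generated.\tPIIC iX: ixsurv006
7/30/14 1:24\t9109-S1\t*** Desat 8 < 80 Generated.\tPIIC iX: ixsurv006
8/11/14 11:59\t9097-S1\t*** Desat 44 < 50 Generated.\tPIIC iX: ixsurv007
8/12/14 10:43\t9113-S1\t*** Desat 80 < 83 Generated.\tPIIC iX: ixsurv006
9/5/14 21:38\t9123-S1\t*** Desat 0 < 78 Generated.\tPIIC iX: ixsurv005
"""

# The same heart-rate threshold crossing logged at advisory (*) and
# yellow (**) priority on different monitors — an inconsistency the
# priority audit should flag.
SAMPLE_HR_PRIORITY_PAIR = """\
Date\tBed label\tMRN\tAlarm and Action\tDevice name
5/2/14 10:15:00\t9101-S1\t0000000\t*HR 153>150 Generated.\tPIIC iX: ixsurv006
5/2/14 11:42:00\t9119-S1\t0000000\t**HR 153 >150 Generated.\tPIIC iX: ixsurv007
"""


def _load(text: str) -> list[AuditRecord]:
    return read_audit_log(io.BytesIO(text.encode("utf-8")), dialect="\t")


def load_sample_unit_log() -> list[AuditRecord]:
    return _load(SAMPLE_UNIT_LOG)


def load_sample_desat_limits() -> list[AuditRecord]:
    return _load(SAMPLE_DESAT_LIMITS)


def load_sample_hr_priority_pair() -> list[AuditRecord]:
    return _load(SAMPLE_HR_PRIORITY_PAIR)
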