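"""Chain hand-built service contacts into care pathways and classify them.

Demonstrates the 24-hour chaining rule, the S/E/A/M letter encoding, the
per-mental-health-call duplication, and anchored classification.
"""

import pandas as pd

from carepath import classify_pathway, duplicate_per_mh_call, link_contacts
from carepath.pathways import Contact


def c(cid, cls, start, end=None, code=None):
    return Contact(cid, "P1", cls, pd.Timestamp(start),
                   pd.Timestamp(end) if end else None, ampds_code=code)


# An ambulance call, transport to the ED, discharge, and a return ED visit
# the next morning: one continuous pathway coded "SEE".
contacts = [
    c("S1", "S", "2011-03-01 22:10", "2011-03-01 22:40", code="25B03"),
    c("E1", "E", "2011-03-01 23:05", "2011-03-02 01:20"),
    c("E2", "E", "2011-03-02 09:40", "2011-03-02 11:00"),
]
pathways = link_contacts(contacts)
print("one pathway:", [p.code_string for p in pathways])

# A second ambulance call 25 h after the last contact starts a NEW pathway.
contacts.append(c("S2", "S", "2011-03-03 12:30", "2011-03-03 13:00", code="25B03"))
pathways = link_contacts(contacts)
print("after a 25 h gap:", [p.code_string for p in pathways])

# A pathway with two mental-health calls is duplicated, one row per call.
seese = [
    c("S1", "S", "2011-05-01 10:00", "2011-05-01 10:30", code="25A01"),
    c("E1", "E", "2011-05-01 11:00", "2011-05-01 13:00"),
    c("E2", "E", "2011-05-01 20:00", "2011-05-01 22:00"),
    c("S2", "S", "2011-05-02 09:00", "2011-05-02 09:30", code="25B03"),
    c("E3", "E", "2011-05-02 10:00", "2011-05-02 12:00"),
]
rows = duplicate_per_mh_call(link_contacts(seese))
print(f"'SEESE' yields {len(rows)} rows, anchored at positions "
      f"{[r.anchor_index for r in rows]}")
for r in rows:
    suffix = r.pathway.code_string[r.anchor_index:]
    print(f"  anchor {r.anchor.contact_id}: suffix {suffix!r} -> class "
          f"{classify_pathway(r.pathway.code_string, r.anchor_index)}")
# The first call reads the whole string (class OTHER); the second reads the
# trailing "SE" (transported to ED and discharged).
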