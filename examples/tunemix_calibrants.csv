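# Editable calibrant reference table for single-field CCS calibration.
# Rows list the singly charged positive-mode tune-mix ions commonly used on
# drift-tube IM-QTOF instruments, with nitrogen reference CCS values as
# compiled in the community single-field interlaboratory studies.  Verify
# these against your own laboratory's accepted values before use; the fit
# consumes whatever reference CCS values this file provides.
calibrant_id,mz,z,ccs_ref
TUNEMIX_118,118.0863,1,121.30
TUNEMIX_322,322.0481,1,153.73
TUNEMIX_622,622.0290,1,202.96
TUNEMIX_922,922.0098,1,243.64
TUNEMIX_1222,1221.9906,1,282.20
TUNEMIX_1522,1521.9715,1,316.72
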