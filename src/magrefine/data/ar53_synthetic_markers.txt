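# Synthetic placeholder identifiers for the default archaeal single-copy
# marker-gene set (53 markers, mirroring the size of the GTDB ar53 set).
# Replace with the real GTDB marker accessions matching your HMM library
# for real analyses; scoring depends only on set membership.
AR53_001
AR53_002
AR53_003
AR53_004
AR53_005
AR53_006
AR53_007
AR53_008
AR53_009
AR53_010
AR53_011
AR53_012
AR53_013
AR53_014
AR53_015
AR53_016
AR53_017
AR53_018
AR53_019
AR53_020
AR53_021
AR53_022
AR53_023
AR53_024
AR53_025
AR53_026
AR53_027
AR53_028
AR53_029
AR53_030
AR53_031
AR53_032
AR53_033
AR53_034
AR53_035
AR53_036
AR53_037
AR53_038
AR53_039
AR53_040
AR53_041
AR53_042
AR53_043
AR53_044
AR53_045
AR53_046
AR53_047
AR53_048
AR53_049
AR53_050
AR53_051
AR53_052
AR53_053
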