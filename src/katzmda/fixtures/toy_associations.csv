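disease_id,metabolite_id
d000,m000
d000,m002
d000,m004
d000,m005
d000,m006
d000,m012
d000,m013
d000,m014
d000,m017
d001,m000
d001,m005
d001,m013
d001,m010
d001,m011
d002,m000
d002,m002
d002,m004
d002,m005
d002,m010
d002,m011
d002,m001
d002,m007
d002,m008
d003,m000
d003,m006
d003,m013
d003,m001
d003,m009
d004,m004
d004,m005
d004,m006
d004,m014
d004,m011
d004,m001
d004,m007
d004,m003
d005,m020
d005,m022
d005,m024
d005,m025
d005,m027
d005,m028
d005,m029
d005,m040
d006,m017
d006,m024
d006,m025
d006,m029
d006,m016
d006,m018
d006,m021
d006,m023
d006,m026
d007,m022
d007,m024
d007,m027
d007,m029
d007,m016
d007,m021
d007,m023
d007,m019
d008,m012
d008,m020
d008,m022
d008,m024
d008,m025
d008,m027
d008,m028
d008,m016
d008,m023
d008,m019
d008,m015
d009,m017
d009,m008
d009,m020
d009,m027
d009,m028
d009,m018
d009,m023
d009,m019
d009,m046
d009,m058
d010,m012
d010,m040
d010,m030
d010,m032
d010,m033
d010,m034
d010,m035
d010,m037
d010,m041
d010,m042
d010,m044
d011,m041
d011,m044
d012,m040
d012,m058
d012,m032
d012,m041
d012,m042
d012,m044
d012,m038
d012,m039
d012,m043
d013,m032
d013,m034
d013,m035
d013,m041
d013,m044
d013,m038
d013,m043
d013,m031
d013,m055
d014,m033
d014,m034
d014,m035
d014,m041
d014,m042
d014,m038
d014,m039
d014,m043
d014,m036
d014,m056
d015,m046
d015,m045
d015,m048
d015,m050
d015,m051
d016,m022
d016,m055
d016,m048
d016,m054
d016,m059
d017,m054
d017,m049
d017,m052
d017,m057
d018,m024
d018,m046
d018,m055
d018,m051
d018,m054
d018,m052
d018,m057
d018,m047
d019,m045
d019,m050
d019,m049
d019,m047
d019,m053
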