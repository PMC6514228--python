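item_id,source_scale,domain,label,a,b1,b2,b3,b4
IAT-3,IAT,mood modification,Excitement,1.587,-0.540,1.054,2.425,3.092
IAT-6,IAT,negative outcomes,Work suffer,1.369,-1.365,0.098,1.724,3.213
IAT-8,IAT,negative outcomes,Job suffer,1.292,-1.352,0.071,1.723,3.351
IAT-10,IAT,mood modification,Block disturbing,1.072,-1.545,0.057,2.049,3.772
IAT-11,IAT,tolerance,Anticipating,1.236,-1.447,0.204,1.656,2.945
IAT-12,IAT,withdrawal,Boring and joyless,1.284,-1.344,-0.202,1.356,2.633
IAT-13,IAT,withdrawal,Annoyed,1.473,-0.466,1.175,2.519,3.457
IAT-14,IAT,negative outcomes,Lose sleep,1.397,-0.932,0.499,1.846,3.331
IAT-15,IAT,salience,Preoccupied,1.863,-0.521,0.797,2.140,3.144
IAT-17,IAT,relapse,Fail to reduce time,1.474,-1.258,0.027,1.415,2.648
IAT-18,IAT,negative outcomes,Hide online time,1.302,-0.238,1.255,2.694,3.956
IAT-19,IAT,salience,Prefer online,1.630,-0.190,1.079,2.316,3.149
IAT-20,IAT,withdrawal,Depressed or nervous,1.972,-0.183,1.133,2.298,3.202
GPIUS-24,GPIUS,mood modification,Feel better,1.352,-1.352,-0.303,0.838,2.852
GPIUS-29,GPIUS,benefits,Treated better,1.324,-0.725,0.600,1.916,3.438
GPIUS-32,GPIUS,benefits,Feel worthless offline,1.397,0.217,1.532,2.541,4.121
GPIUS-33,GPIUS,negative outcomes,Missed social event,1.298,-0.274,0.975,2.092,3.320
GPIUS-34,GPIUS,relapse,Unsuccessful,1.602,-0.829,0.277,1.209,2.686
GPIUS-35,GPIUS,relapse,Fail to reduce time,1.631,-0.659,0.452,1.495,2.661
GPIUS-38,GPIUS,tolerance,Forget the time,1.101,-1.525,-0.367,0.595,2.595
GPIUS-41,GPIUS,tolerance,Longer time,1.404,-1.477,-0.382,0.495,2.531
GPIUS-43,GPIUS,withdrawal,Miss,1.657,-0.976,0.078,0.939,2.545
GPIUS-44,GPIUS,withdrawal,Wonder,1.335,-1.230,-0.074,0.836,2.867
GPIUS-45,GPIUS,withdrawal,Feel lost,1.856,-0.675,0.358,1.225,2.696
GPIUS-46,GPIUS,tolerance,Unable to stop thinking,1.659,-0.578,0.516,1.481,2.785
GPIUS-49,GPIUS,benefits,Control,1.247,-0.400,0.858,2.204,3.795
GAS-55,GAS,tolerance,Unable to stop playing,1.381,-0.418,0.848,2.147,3.081
GAS-56,GAS,mood modification,Forget about real life,1.534,-0.099,1.211,2.602,3.401
GAS-59,GAS,relapse,Unable to reduce time,1.490,-0.207,1.163,2.294,3.205
GAS-65,GAS,negative outcomes,Fights with others,1.719,-0.173,0.960,2.179,3.142
GAS-66,GAS,negative outcomes,Neglected others,1.787,-0.365,0.635,1.967,2.995
GAS-68,GAS,negative outcomes,Lose sleep,1.721,-0.320,0.777,1.948,2.795
GAS-70,GAS,negative outcomes,Feel bad,1.195,-1.299,-0.119,1.611,3.131
CIAT-71,CIAT,negative outcomes,Neglect household,1.984,-0.722,0.462,1.687,2.714
CIAT-72,CIAT,mood modification,Excitement,2.294,-0.374,0.794,1.806,2.629
CIAT-74,CIAT,negative outcomes,Complain of others,1.745,-0.449,0.906,2.061,2.981
CIAT-75,CIAT,negative outcomes,School or work suffer,1.879,-0.848,0.334,1.544,2.628
CIAT-76,CIAT,negative outcomes,Defensive or secretive,1.189,-0.845,0.767,2.322,3.384
CIAT-77,CIAT,mood modification,Disturbing,1.631,-1.006,0.152,1.614,2.733
CIAT-78,CIAT,tolerance,Anticipating,1.975,-0.742,0.445,1.695,2.513
CIAT-79,CIAT,withdrawal,Annoyed act,1.831,-0.176,1.157,2.132,2.994
CIAT-80,CIAT,negative outcomes,Lose sleep,1.456,-0.498,0.739,1.975,2.876
CIAT-81,CIAT,salience,Preoccupied,2.639,-0.404,0.728,1.782,2.407
CIAT-82,CIAT,relapse,Just a few minutes,2.053,-0.866,0.206,1.354,2.421
CIAT-83,CIAT,negative outcomes,Hide online time,1.873,-0.207,1.095,2.122,3.108
CIAT-84,CIAT,tolerance,Spend more time,2.409,-0.375,0.556,1.429,2.242
CIAT-85,CIAT,salience,Important,2.077,-0.343,0.631,1.630,2.521
CIAT-86,CIAT,benefits,More attractive,2.093,-0.337,0.744,1.904,2.795
CIAT-88,CIAT,benefits,Exciting information,1.382,-1.450,-0.112,1.581,2.845
CIAT-91,CIAT,benefits,Reduce the stress,1.443,-1.298,-0.006,1.659,2.918
CIAT-92,CIAT,tolerance,Times goes faster,1.189,-1.968,-0.854,0.511,2.143
CIAT-93,CIAT,tolerance,Stay online,2.192,-0.787,0.404,1.380,2.349
CIAT-94,CIAT,withdrawal,Want to stay online,2.233,-0.825,0.421,1.605,2.350
CIAT-95,CIAT,withdrawal,Disturbed,1.219,-1.951,-0.632,0.800,2.250
CIAT-96,CIAT,withdrawal,Distraught,1.894,-0.713,0.511,1.622,2.621
CIAT-97,CIAT,relapse,Failed to reduce time,2.103,-0.698,0.493,1.575,2.443
CIAT-98,CIAT,salience,Addiction,1.391,-1.158,-0.098,1.259,2.499
CIAT-99,CIAT,salience,Addiction,1.675,-0.579,0.721,1.796,2.730
CIAT-101,CIAT,relapse,Dependent,1.504,-0.308,1.141,2.388,3.182
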