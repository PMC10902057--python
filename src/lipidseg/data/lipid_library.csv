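name,class,carbons,double_bonds,ether,formula,neutral_mass,mz_MH
SM 34:1,SM,34,1,0,C39H79N2O6P1,702.567575,701.560298
PE 34:1,PE,34,1,0,C39H76N1O8P1,717.530855,716.523579
PC 32:0e,PC-E,32,0,1,C40H82N1O7P1,719.582891,718.575614
PE 36:5e,PE-E,36,5,1,C41H74N1O7P1,723.52029,722.513014
PE 36:2e,PE-E,36,2,1,C41H80N1O7P1,729.567241,728.559964
SM 36:1,SM,36,1,0,C41H83N2O6P1,730.598875,729.591599
PC 32:0,PC,32,0,0,C40H80N1O8P1,733.562155,732.554879
PE 36:2,PE,36,2,0,C41H78N1O8P1,743.546505,742.539229
PE 36:1,PE,36,1,0,C41H80N1O8P1,745.562155,744.554879
PC 34:1e,PC-E,34,1,1,C42H84N1O7P1,745.598541,744.591264
PE 38:7e,PE-E,38,7,1,C43H74N1O7P1,747.52029,746.513014
PG 34:1,PG,34,1,0,C40H77O10P1,748.525435,747.518159
PE 38:6e,PE-E,38,6,1,C43H76N1O7P1,749.53594,748.528664
SM 38:1,SM,38,1,0,C43H87N2O6P1,758.630175,757.622899
PC 34:1,PC,34,1,0,C42H82N1O8P1,759.577805,758.570529
PC 34:0,PC,34,0,0,C42H84N1O8P1,761.593455,760.586179
PE 38:6,PE,38,6,0,C43H74N1O8P1,763.515205,762.507929
PE 38:4,PE,38,4,0,C43H78N1O8P1,767.546505,766.539229
PC 36:4e,PC-E,36,4,1,C44H82N1O7P1,767.582891,766.575614
PG 36:2,PG,36,2,0,C42H79O10P1,774.541085,773.533809
PE 40:7e,PE-E,40,7,1,C45H78N1O7P1,775.55159,774.544314
PE 40:6e,PE-E,40,6,1,C45H80N1O7P1,777.567241,776.559964
PC 36:4,PC,36,4,0,C44H80N1O8P1,781.562155,780.554879
PS 36:2,PS,36,2,0,C42H78N1O10P1,787.536334,786.529058
PC 36:1,PC,36,1,0,C44H86N1O8P1,787.609105,786.601829
PS 36:1,PS,36,1,0,C42H80N1O10P1,789.551984,788.544708
PE 40:6,PE,40,6,0,C45H78N1O8P1,791.546505,790.539229
PC 38:5e,PC-E,38,5,1,C46H84N1O7P1,793.598541,792.591264
PG 38:4,PG,38,4,0,C44H79O10P1,798.541085,797.533809
PC 38:6,PC,38,6,0,C46H80N1O8P1,805.562155,804.554879
PC 38:4,PC,38,4,0,C46H84N1O8P1,809.593455,808.586179
PS 38:4,PS,38,4,0,C44H78N1O10P1,811.536334,810.529058
SM 42:2,SM,42,2,0,C47H93N2O6P1,812.677125,811.669849
PG 40:6,PG,40,6,0,C46H79O10P1,822.541085,821.533809
PC 40:6,PC,40,6,0,C48H84N1O8P1,833.593455,832.586179
PS 40:6,PS,40,6,0,C46H78N1O10P1,835.536334,834.529058
PI 34:1,PI,34,1,0,C43H81O13P1,836.541479,835.534203
PS 40:4,PS,40,4,0,C46H82N1O10P1,839.567634,838.560358
PI 36:4,PI,36,4,0,C45H79O13P1,858.525829,857.518553
PI 36:2,PI,36,2,0,C45H83O13P1,862.557129,861.549853
ST 40:1,ST,40,1,0,C46H89N1O11S1,863.615634,862.608357
PI 36:1,PI,36,1,0,C45H85O13P1,864.572779,863.565503
PI 37:4,PI,37,4,0,C46H81O13P1,872.541479,871.534203
ST 41:1,ST,41,1,0,C47H91N1O11S1,877.631284,876.624007
PI 38:6,PI,38,6,0,C47H79O13P1,882.525829,881.518553
PI 38:5,PI,38,5,0,C47H81O13P1,884.541479,883.534203
PI 38:4,PI,38,4,0,C47H83O13P1,886.557129,885.549853
ST 42:3,ST,42,3,0,C48H89N1O11S1,887.615634,886.608357
ST 42:2,ST,42,2,0,C48H91N1O11S1,889.631284,888.624007
ST 42:1,ST,42,1,0,C48H93N1O11S1,891.646934,890.639657
PI 40:6,PI,40,6,0,C49H83O13P1,910.557129,909.549853
ST 44:1,ST,44,1,0,C50H97N1O11S1,919.678234,918.670957
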