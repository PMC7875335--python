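unit_id,level,region,population,cases,deaths
Rondonia,state,North,1768204,2471,8
Acre,state,North,803513,2389,7
Amazonas,state,North,3938336,8035,50
Roraima,state,North,505665,1842,14
Para,state,North,8175113,25210,82
Amapa,state,North,766679,1842,6
Tocantins,state,North,1515126,3796,13
North,region,,17472636,45492,180
Maranhao,state,Northeast,6904241,6991,43
Piaui,state,Northeast,3204028,1102,6
Ceara,state,Northeast,8904459,3084,15
Rio Grande do Norte,state,Northeast,3442175,1667,3
Paraiba,state,Northeast,3972202,1747,5
Pernambuco,state,Northeast,9345173,3894,22
Alagoas,state,Northeast,3340932,1607,1
Sergipe,state,Northeast,2242937,788,7
Bahia,state,Northeast,15203934,12377,62
Northeast,region,,56560081,33257,164
Minas Gerais,state,Southeast,20869101,14647,35
Espirito Santo,state,Southeast,3929911,3688,7
Rio de Janeiro,state,Southeast,16550024,2753,6
Sao Paulo,state,Southeast,44396484,9441,27
Southeast,region,,85745520,30529,75
Parana,state,South,11163018,4167,13
Santa Catarina,state,South,6819190,3515,8
Rio Grande do Sul,state,South,11247972,4227,12
South,region,,29230180,11909,33
Mato Grosso do Sul,state,Central-West,2651235,2570,6
Mato Grosso,state,Central-West,3265486,6010,28
Goias,state,Central-West,6610681,5329,26
Distrito Federal,state,Central-West,2914830,502,2
Central-West,region,,15442232,14411,62
Brazil,country,,204450649,135598,514
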