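pair,band,slope,intercept
tm_etm_to_oli,blue,0.8474,0.0003
tm_etm_to_oli,green,0.8483,0.0088
tm_etm_to_oli,red,0.9047,0.0061
tm_etm_to_oli,nir,0.8462,0.0412
tm_etm_to_oli,swir1,0.8937,0.0254
tm_etm_to_oli,swir2,0.9071,0.0172
oli_msi,blue,1.0946,-0.0107
oli_msi,green,1.0043,0.0026
oli_msi,red,1.0524,-0.0015
oli_msi,nir,0.8954,0.0033
oli_msi,swir1,1.0049,0.0065
oli_msi,swir2,1.0002,0.0046
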