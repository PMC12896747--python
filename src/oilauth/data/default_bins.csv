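start,end,step
74.99,75.11,0.01
76.0,81.0,0.5
82.0,87.0,0.5
88.0,93.0,0.5
94.0,99.0,0.5
101.04,101.1,0.01
105.54,105.6,0.01
110.05,110.11,0.01
114.55,114.61,0.01
119.05,119.11,0.01
123.56,123.62,0.01
128.06,128.12,0.01
132.56,132.62,0.01
137.07,137.13,0.01
141.57,141.63,0.01
146.07,146.13,0.01
150.58,150.64,0.01
155.08,155.14,0.01
159.58,159.64,0.01
164.08,164.14,0.01
168.59,168.65,0.01
173.09,173.15,0.01
177.59,177.65,0.01
182.1,182.16,0.01
186.6,186.66,0.01
191.1,191.16,0.01
195.61,195.67,0.01
200.11,200.17,0.01
204.61,204.67,0.01
209.12,209.18,0.01
213.62,213.68,0.01
218.12,218.18,0.01
222.63,222.69,0.01
227.13,227.19,0.01
231.63,231.69,0.01
236.14,236.2,0.01
240.64,240.7,0.01
245.14,245.2,0.01
249.64,249.7,0.01
254.15,254.21,0.01
258.65,258.71,0.01
263.15,263.21,0.01
267.66,267.72,0.01
272.16,272.22,0.01
276.66,276.72,0.01
281.17,281.23,0.01
285.67,285.73,0.01
290.17,290.23,0.01
294.68,294.74,0.01
302.0,307.0,0.5
320.0,325.0,0.5
325.2,325.26,0.01
338.0,343.0,0.5
356.0,361.0,0.5
374.0,379.0,0.5
385.24,385.3,0.01
392.0,397.0,0.5
410.0,415.0,0.5
428.0,433.0,0.5
445.28,445.34,0.01
446.0,451.0,0.5
464.0,469.0,0.5
482.0,487.0,0.5
500.0,505.0,0.5
505.32,505.38,0.01
518.0,523.0,0.5
536.0,541.0,0.5
554.0,559.0,0.5
565.37,565.43,0.01
572.0,577.0,0.5
590.0,595.0,0.5
608.0,613.0,0.5
625.41,625.47,0.01
626.0,631.0,0.5
700.0,705.0,0.5
725.0,730.0,0.5
750.0,755.0,0.5
775.0,780.0,0.5
805.53,805.59,0.01
819.54,819.6,0.01
833.55,833.61,0.01
847.56,847.62,0.01
861.57,861.63,0.01
875.58,875.64,0.01
889.59,889.65,0.01
903.6,903.66,0.01
917.61,917.67,0.01
931.62,931.68,0.01
945.63,945.69,0.01
959.64,959.7,0.01
973.65,973.71,0.01
987.66,987.72,0.01
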