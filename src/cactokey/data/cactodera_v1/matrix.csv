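taxon,cyst_length,cyst_width,cyst_lw_ratio,vulval_denticles,fenestral_diam,j2_body_length,dgo,stylet_length,tail_length,hyaline_tail_length,eggshell_surface,citation,notes
C. acnidae,504-857,319-493,1.2-2.4,-,30-33,361-448,2.5-3.0,19-25,43-48,17-26,smooth,original description,two-axis fenestra 30 x 33
C. amaranthi,525-774,370-550,1.1-1.7,present,25-38,340-460,3.9-5.1,20-21,32-40,12-16,smooth,original description,
C. cacti,389-658,323-598,1.0-1.4,present,16-30,456-540,2.9-4.4,24-26,49-60,14-21,punctate,original description,
C. chenopodiae,423-585,283-398,1.2-1.7,absent,20-26,438-539,3.1-4.3,22-26,39-51,17-28,punctate,original description,
C. eremica,530-810,290-590,1.2-1.9,absent,14-25,440-510,3.5-6.0,25-28,36-47,17-23,punctate,original description,
C. estonica,686-1014,312-468,2.0-2.4,present,18-30,426-465,3.4-4.3,22-24,36-44,14-21,smooth,original description,
C. evansi,416-528,284-384,1.2-1.7,-,18-23,358-420,2.8-4.0,20-24,34-44,16-23,punctate,original description,
C. galinsogae,453-675,284-508,1.1-1.7,absent,33-56,358-443,-,19-31,26-45,10-24,punctate,original description,
C. milleri,550-849,419-598,1.2-1.6,present,14-18,370-479,3.2-5.1,21-23,37-49,15-21,punctate,original description,
C. radicale,553-986,220-626,1.3-2.6,absent,17-28,467-520,3.6-5.8,20-27,46-60,15-28,smooth,original description,
C. rosae,460-840,280-560,1.2-2.1,present,10-21,348-472,-,16-26,31-68,4-8,punctate,original description,
C. salina,415-742,193-475,1.4-2.2,absent,20-28,410-514,2.5-4.0,23-25,31-48,10-31,smooth,original description,
C. solani,291-581,204-505,1.2-1.4,present,20-36,379-511,3.7-6.9,24-27,28-49,12-23,punctate,original description,
C. thornei,485-806,286-581,1.2-1.9,present,31-36,446-620,5-7,25-28,49-64,23-28,punctate,original description,
C. tianzhuensis,511-761,361-558,1.1-1.6,present,20-32,495-592,4.0-6.5,23-26,47-59,22-29,smooth,type description,
C. torreyanae,364-712,92-432,1.4-2.9,absent,20-26,390-550,2-4,21-23,32-45,16-25,smooth,original description,two-axis fenestra 20 x 26
C. weissi,524-598,350-394,1.2-2.3,present,29-38,407-489,4.5-5.6,20-22,43-50,17-24,smooth,original description,
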