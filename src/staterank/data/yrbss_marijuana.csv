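state,prevalence_pct,se_pct,published_rank
Alabama,17.1,0.9,33
Alaska,18.9,0.8,23
Arizona,22.3,1.2,8
Arkansas,16.5,0.7,36
California,21.5,2.0,10
Colorado,21.4,1.2,11
Connecticut,22.3,0.8,8
Delaware,23.7,0.8,4
Florida,20.5,0.5,13
Georgia,19.6,1.0,19
Idaho,16.3,0.8,37
Illinois,20.3,0.8,14
Indiana,17.2,0.9,32
Iowa,13.8,1.9,43
Kansas,15.3,0.8,41
Kentucky,16.7,0.8,35
Louisiana,16.4,1.1,37
Maine,19.6,0.5,18
Maryland,19.6,0.5,18
Massachusetts,24.6,0.8,2
Michigan,17.4,0.6,31
Mississippi,17.3,0.7,31
Missouri,17.2,1.1,32
Montana,19.8,0.7,17
Nebraska,12.5,0.8,45
Nevada,18.6,1.1,24
New Hampshire,23.2,0.9,5
New Jersey,18.9,1.0,23
New Mexico,27.1,1.2,1
New York,19.0,0.7,22
North Carolina,22.3,0.9,8
North Dakota,14.5,0.8,42
Ohio,20.3,1.4,15
Oklahoma,16.6,1.0,35
Pennsylvania,17.0,1.1,34
Rhode Island,23.3,0.8,5
South Carolina,19.7,0.9,18
South Dakota,14.2,1.5,43
Tennessee,20.0,0.8,16
Texas,19.5,0.8,19
Utah,8.2,0.7,46
Vermont,22.4,0.7,8
Virginia,16.6,0.7,36
West Virginia,17.5,0.8,30
Wisconsin,17.8,1.1,29
Wyoming,18.2,0.7,26
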